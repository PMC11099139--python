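"""Map-dump parsing, SCPN grammar, deduplication and promiscuity bins."""

import random

import pytest
from hypothesis import given, strategies as st

from patentchem.errors import IngestError, ScpnParseError
from patentchem.ingest import (
    ColumnMap,
    CompoundOccurrence,
    KindGroup,
    PatentRef,
    SectionSource,
    dedupe,
    format_scpn,
    kind_group,
    parse_scpn,
    promiscuity_distribution,
    read_map_dump,
)

K1 = "AAAAAAAAAAAAAA-BBBBBBBBBB-N"
K2 = "CCCCCCCCCCCCCC-DDDDDDDDDD-N"
K3 = "EEEEEEEEEEEEEE-FFFFFFFFFF-N"

HEADER = "SCHEMBL_ID\tSMILES\tInChIKey\tFrequency\tPatent_ID\tPublication_Date\tField"


def write_dump(path, rows):
    path.write_text("\n".join([HEADER, *rows]) + "\n")
    return path


def row(cid="SCHEMBL1", smiles="CCO", key=K1, patent="US-1234567-A1",
        date="2016-03-01", field="5"):
    return f"{cid}\t{smiles}\t{key}\t1\t{patent}\t{date}\t{field}"


class TestScpn:
    def test_parses_example_identifier(self):
        ref = parse_scpn("US-1234567-A1")
        assert (ref.country, ref.serial, ref.kind) == ("US", "1234567", "A1")

    def test_upper_bound_serial_length(self):
        ref = parse_scpn("EP-12345678901-B1")
        assert len(ref.serial) == 11 and ref.kind == "B1"

    @pytest.mark.parametrize(
        "scpn, component",
        [
            ("US-123456-A1", "serial"),      # 6 digits
            ("US-123456789012-A1", "serial"),  # 12 digits
            ("USA-1234567-A1", "country"),
            ("u1-1234567-A1", "country"),
            ("US-1234567-1A", "kind"),
            ("US-1234567-A12", "kind"),
            ("US1234567A1", "format"),
            ("", "format"),
        ],
    )
    def test_malformed_identifiers_name_the_component(self, scpn, component):
        with pytest.raises(ScpnParseError) as err:
            parse_scpn(scpn)
        assert err.value.component == component

    @given(
        country=st.text(alphabet=st.characters(min_codepoint=65, max_codepoint=90),
                        min_size=2, max_size=2),
        serial=st.integers(min_value=0, max_value=10**11 - 1).map(
            lambda n: str(n).zfill(7)
        ),
        kind=st.from_regex(r"[A-Z][0-9]?", fullmatch=True),
    )
    def test_roundtrip_on_grammar_valid_identifiers(self, country, serial, kind):
        scpn = f"{country}-{serial}-{kind}"
        assert format_scpn(parse_scpn(scpn)) == scpn


class TestKindGroup:
    @pytest.mark.parametrize(
        "kind, group",
        [
            ("A1", KindGroup.FILED),
            ("A2", KindGroup.FILED),
            ("B2", KindGroup.GRANTED),
            ("S1", KindGroup.OTHER),
            ("E1", KindGroup.OTHER),
            ("P1", KindGroup.OTHER),
        ],
    )
    def test_leading_letter_decides_group(self, kind, group):
        assert kind_group(kind) is group

    def test_unenumerated_letter_falls_back_to_other(self, caplog):
        with caplog.at_level("WARNING"):
            assert kind_group("X1") is KindGroup.OTHER
        assert any("X1" in m for m in caplog.messages)


class TestReadMapDump:
    def test_valid_rows_load_without_drops(self, tmp_path):
        dump = write_dump(
            tmp_path / "d.tsv",
            [row(key=K1), row(key=K2, patent="EP-7654321-B1"), row(key=K3)],
        )
        occurrences, report = read_map_dump(dump)
        assert len(occurrences) == 3
        assert report.rows_read == 3 and report.rows_dropped == 0

    def test_invalid_inchikey_dropped_and_counted(self, tmp_path):
        dump = write_dump(tmp_path / "d.tsv", [row(), row(key="XYZ")])
        occurrences, report = read_map_dump(dump)
        assert len(occurrences) == 1
        assert report.dropped == {"invalid_inchikey": 1}

    def test_invalid_scpn_dropped_and_counted(self, tmp_path):
        dump = write_dump(tmp_path / "d.tsv", [row(), row(key=K2, patent="US-12-A1")])
        _, report = read_map_dump(dump)
        assert report.dropped == {"invalid_scpn": 1}

    def test_sections_merge_per_compound_patent_pair(self, tmp_path):
        dump = write_dump(tmp_path / "d.tsv", [row(field="2"), row(field="5")])
        occurrences, _ = read_map_dump(dump)
        assert len(occurrences) == 1
        assert occurrences[0].sections == frozenset(
            {SectionSource.CLAIMS, SectionSource.IMAGE}
        )

    def test_pre_2015_rows_excluded_by_default(self, tmp_path):
        dump = write_dump(
            tmp_path / "d.tsv", [row(), row(key=K2, date="2014-12-31")]
        )
        occurrences, report = read_map_dump(dump)
        assert len(occurrences) == 1
        assert report.dropped == {"before_min_year": 1}
        occurrences, _ = read_map_dump(dump, min_year=None)
        assert len(occurrences) == 2

    def test_missing_file_and_missing_column_are_fatal(self, tmp_path):
        with pytest.raises(IngestError):
            read_map_dump(tmp_path / "absent.tsv")
        bad = tmp_path / "bad.tsv"
        bad.write_text("a\tb\nc\td\n")
        with pytest.raises(IngestError, match="Patent_ID"):
            read_map_dump(bad)

    def test_empty_file_yields_empty_list(self, tmp_path):
        dump = tmp_path / "empty.tsv"
        dump.write_text(HEADER + "\n")
        occurrences, report = read_map_dump(dump)
        assert occurrences == [] and report.rows_read == 0

    def test_custom_column_map(self, tmp_path):
        dump = tmp_path / "d.tsv"
        dump.write_text(
            "id\tsmi\tkey\tpat\twhen\tsrc\n"
            f"SCHEMBL9\tCCO\t{K1}\tUS-1234567-A1\t2017-01-01\t1\n"
        )
        cmap = ColumnMap(
            compound_id="id", smiles="smi", inchikey="key", frequency="freq",
            patent_id="pat", date="when", section="src",
        )
        occurrences, _ = read_map_dump(dump, cmap)
        assert occurrences[0].sections == frozenset({SectionSource.DESCRIPTION})


def occ(key, scpn, year, sections, smiles="CCO"):
    return CompoundOccurrence(
        schembl_id="SCHEMBL1",
        smiles=smiles,
        inchikey=key,
        patent=parse_scpn(scpn, year=year),
        sections=frozenset(sections),
    )


class TestDedupe:
    def test_unions_patents_and_takes_min_year(self):
        records = dedupe(
            [
                occ(K1, "US-1111111-A1", 2016, {SectionSource.IMAGE}),
                occ(K1, "EP-2222222-B1", 2015, {SectionSource.CLAIMS}),
            ]
        )
        assert len(records) == 1
        rec = records[0]
        assert rec.n_patents == 2
        assert rec.first_year == 2015
        assert rec.sections == frozenset({SectionSource.IMAGE, SectionSource.CLAIMS})

    def test_five_occurrences_three_keys(self):
        occurrences = [
            occ(K1, "US-1111111-A1", 2016, {SectionSource.TITLE}),
            occ(K1, "US-1111112-A1", 2017, {SectionSource.IMAGE}),
            occ(K2, "US-1111113-A1", 2018, {SectionSource.CLAIMS}),
            occ(K2, "US-1111113-A1", 2018, {SectionSource.CLAIMS}),
            occ(K3, "US-1111114-B1", 2015, {SectionSource.MOLFILE}),
        ]
        records = {r.inchikey: r for r in dedupe(occurrences)}
        assert set(records) == {K1, K2, K3}
        assert {p.scpn for p in records[K1].patents} == {
            "US-1111111-A1", "US-1111112-A1"
        }
        assert records[K2].n_patents == 1
        assert records[K3].first_year == 2015

    def test_idempotent_and_order_independent(self):
        occurrences = [
            occ(K1, "US-1111111-A1", 2016, {SectionSource.TITLE}),
            occ(K2, "US-1111112-A1", 2015, {SectionSource.IMAGE}),
            occ(K1, "EP-1111113-B1", 2018, {SectionSource.CLAIMS}),
        ]
        base = dedupe(occurrences)
        rng = random.Random(0)
        for _ in range(5):
            shuffled = occurrences[:]
            rng.shuffle(shuffled)
            assert dedupe(shuffled) == base
        assert dedupe([]) == []

    def test_sections_equal_union_of_occurrence_sections(self, small_corpus):
        _, paths, _ = small_corpus
        occurrences, _ = read_map_dump(paths.map_file)
        records = {r.inchikey: r for r in dedupe(occurrences)}
        union = {}
        for o in occurrences:
            union.setdefault(o.inchikey, set()).update(o.sections)
        assert all(records[k].sections == frozenset(v) for k, v in union.items())


class TestPromiscuity:
    def make_records(self, counts):
        occurrences = []
        for i, c in enumerate(counts):
            key = f"{chr(65 + i) * 14}-{'Q' * 10}-N"
            for j in range(c):
                occurrences.append(
                    occ(key, f"US-{1000000 + i * 3000 + j}-A1", 2016, {SectionSource.IMAGE})
                )
        return dedupe(occurrences)

    def test_all_singletons(self):
        hist = promiscuity_distribution(self.make_records([1, 1, 1]))
        assert hist.bins == {"1": 3, "2-4": 0, "5-1000": 0, ">1000": 0}

    def test_bin_edges_at_5_and_1000(self):
        hist = promiscuity_distribution(self.make_records([4, 5, 1000, 1001]))
        assert hist.bins == {"1": 0, "2-4": 1, "5-1000": 2, ">1000": 1}

    def test_bin_counts_sum_to_record_count(self, small_corpus):
        _, paths, truth = small_corpus
        occurrences, _ = read_map_dump(paths.map_file)
        records = dedupe(occurrences)
        hist = promiscuity_distribution(records)
        assert sum(hist.bins.values()) == len(records)
        # independent recount from the ground-truth planted patent counts
        expected = {"1": 0, "2-4": 0, "5-1000": 0, ">1000": 0}
        for comp in truth["compounds"]:
            c = comp["n_patents"]
            expected[
                "1" if c == 1 else "2-4" if c <= 4 else "5-1000" if c <= 1000 else ">1000"
            ] += 1
        assert hist.bins == expected
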