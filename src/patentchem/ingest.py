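"""Reading SureChEMBL-style compound-to-patent map dumps.

A map dump is a tab-separated text file with one row per annotation event:
a compound (SCHEMBL accession, SMILES, InChIKey) seen in one patent document
(SCPN identifier, publication date) through one annotation source (title,
abstract, description, claims, chemical image or molfile).  This module
parses the patent identifiers, decodes the annotation sources, validates
rows, and collapses the stream into per-compound records keyed by InChIKey.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import IngestError, ScpnParseError

logger = logging.getLogger(__name__)

#: SCPN grammar: 2-letter jurisdiction, 7-11 digit serial, kind code.
_COUNTRY_RE = re.compile(r"^[A-Z]{2}$")
_SERIAL_RE = re.compile(r"^[0-9]{7,11}$")
_KIND_RE = re.compile(r"^[A-Z][0-9]?$")

#: Full 27-character InChIKey: 14-char connectivity block, 10-char
#: stereo/isotope block, protonation flag.
INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class KindGroup(enum.Enum):
    """Patent publication type derived from the leading kind-code letter.

    A* marks a filed application, B* a granted patent; design (S*),
    reissue (E*) and plant (P*) documents are grouped as OTHER.
    """

    FILED = "filed"
    GRANTED = "granted"
    OTHER = "other"


class SectionSource(enum.Enum):
    """The six sources a compound annotation can come from."""

    TITLE = "title"
    ABSTRACT = "abstract"
    DESCRIPTION = "description"
    CLAIMS = "claims"
    IMAGE = "image"
    MOLFILE = "molfile"


#: Default integer field-code encoding used in map dumps (overridable).
DEFAULT_SECTION_CODES: Mapping[int, SectionSource] = {
    1: SectionSource.DESCRIPTION,
    2: SectionSource.CLAIMS,
    3: SectionSource.ABSTRACT,
    4: SectionSource.TITLE,
    5: SectionSource.IMAGE,
    6: SectionSource.MOLFILE,
}


@dataclass(frozen=True, order=True)
class PatentRef:
    """A parsed SCPN patent identifier plus its application year."""

    country: str
    serial: str
    kind: str
    year: int | None = None

    @property
    def scpn(self) -> str:
        return f"{self.country}-{self.serial}-{self.kind}"


def parse_scpn(scpn: str, year: int | None = None) -> PatentRef:
    """Parse a ``COUNTRY-SERIAL-KIND`` patent identifier.

    Raises :class:`ScpnParseError` naming the offending component when the
    identifier does not follow the grammar (2 uppercase letters, 7-11
    digits, one uppercase letter plus optional digit).
    """
    if not isinstance(scpn, str) or not scpn:
        raise ScpnParseError(str(scpn), "format", "empty or non-string identifier")
    parts = scpn.split("-")
    if len(parts) != 3:
        raise ScpnParseError(scpn, "format", "expected COUNTRY-SERIAL-KIND")
    country, serial, kind = parts
    if not _COUNTRY_RE.match(country):
        raise ScpnParseError(scpn, "country", f"bad jurisdiction code {country!r}")
    if not _SERIAL_RE.match(serial):
        raise ScpnParseError(scpn, "serial", f"serial {serial!r} not 7-11 digits")
    if not _KIND_RE.match(kind):
        raise ScpnParseError(scpn, "kind", f"bad kind code {kind!r}")
    return PatentRef(country=country, serial=serial, kind=kind, year=year)


def format_scpn(ref: PatentRef) -> str:
    """Inverse of :func:`parse_scpn` (ignores the year)."""
    return ref.scpn


def kind_group(kind: str) -> KindGroup:
    """Map a kind code to filed / granted / other."""
    letter = kind[:1]
    if letter == "A":
        return KindGroup.FILED
    if letter == "B":
        return KindGroup.GRANTED
    if letter not in ("S", "E", "P"):
        logger.warning("unenumerated kind-code letter %r; grouping as OTHER", kind)
    return KindGroup.OTHER


@dataclass(frozen=True)
class ColumnMap:
    """Logical-to-physical column names of a map dump.

    The dump dialect is not standardized; the defaults follow the layout
    (accession, SMILES, InChIKey, corpus frequency, patent id, publication
    date, field code) and can be overridden per file.
    """

    compound_id: str = "SCHEMBL_ID"
    smiles: str = "SMILES"
    inchikey: str = "InChIKey"
    frequency: str = "Frequency"
    patent_id: str = "Patent_ID"
    date: str = "Publication_Date"
    section: str = "Field"

    def required(self) -> Sequence[str]:
        return (
            self.compound_id,
            self.smiles,
            self.inchikey,
            self.patent_id,
            self.date,
            self.section,
        )


@dataclass(frozen=True)
class CompoundOccurrence:
    """One (compound, patent) pair with the union of its annotation sources."""

    schembl_id: str
    smiles: str
    inchikey: str
    patent: PatentRef
    sections: frozenset[SectionSource]


@dataclass
class LoadReport:
    """Row accounting for one map-dump load."""

    path: str = ""
    rows_read: int = 0
    rows_kept: int = 0
    occurrences: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def rows_dropped(self) -> int:
        return sum(self.dropped.values())

    def to_dict(self) -> dict:
        return {
            "path": self.path,
            "rows_read": self.rows_read,
            "rows_kept": self.rows_kept,
            "rows_dropped": self.rows_dropped,
            "occurrences": self.occurrences,
            "dropped_by_reason": dict(sorted(self.dropped.items())),
        }


def read_map_dump(
    path: str | Path,
    column_map: ColumnMap | None = None,
    *,
    min_year: int | None = 2015,
    section_codes: Mapping[int, SectionSource] | None = None,
) -> tuple[list[CompoundOccurrence], LoadReport]:
    """Read a tab-separated (optionally gzipped) map dump.

    Rows with an unparsable SCPN, an invalid InChIKey, an unusable date or
    an unknown section code are dropped (never repaired) and counted by
    reason.  Rows before ``min_year`` are excluded by default, mirroring the
    exclusion of the pre-2015 legacy data whose format lacks patent
    information.  Returns the merged (compound, patent) occurrences and a
    :class:`LoadReport`.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"map dump not found: {path}")
    cmap = column_map or ColumnMap()
    codes = dict(section_codes or DEFAULT_SECTION_CODES)

    report = LoadReport(path=str(path))
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("map dump %s is empty", path)
        return [], report

    missing = [c for c in cmap.required() if c not in df.columns]
    if missing:
        raise IngestError(f"map dump {path} lacks mapped column(s): {missing}")

    report.rows_read = len(df)
    if df.empty:
        logger.warning("map dump %s has a header but no rows", path)
        return [], report

    merged: dict[tuple[str, str], dict] = {}
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        inchikey = rec[cmap.inchikey].strip()
        if not INCHIKEY_RE.match(inchikey):
            report.drop("invalid_inchikey")
            continue
        try:
            year = int(str(rec[cmap.date]).strip()[:4])
        except (ValueError, TypeError):
            report.drop("invalid_date")
            continue
        try:
            patent = parse_scpn(rec[cmap.patent_id].strip(), year=year)
        except ScpnParseError:
            report.drop("invalid_scpn")
            continue
        if min_year is not None and year < min_year:
            report.drop("before_min_year")
            continue
        try:
            section = codes[int(str(rec[cmap.section]).strip())]
        except (KeyError, ValueError):
            report.drop("unknown_section")
            continue

        key = (inchikey, patent.scpn)
        slot = merged.setdefault(
            key,
            {
                "schembl_id": rec[cmap.compound_id].strip(),
                "smiles": rec[cmap.smiles].strip(),
                "patent": patent,
                "sections": set(),
            },
        )
        slot["sections"].add(section)
        report.rows_kept += 1

    occurrences = [
        CompoundOccurrence(
            schembl_id=slot["schembl_id"],
            smiles=slot["smiles"],
            inchikey=key[0],
            patent=slot["patent"],
            sections=frozenset(slot["sections"]),
        )
        for key, slot in merged.items()
    ]
    report.occurrences = len(occurrences)
    return occurrences, report


@dataclass(frozen=True)
class CompoundRecord:
    """A deduplicated compound: one record per distinct InChIKey."""

    inchikey: str
    smiles: str
    patents: frozenset[PatentRef]
    sections: frozenset[SectionSource]
    first_year: int

    @property
    def n_patents(self) -> int:
        return len(self.patents)

    @property
    def years(self) -> frozenset[int]:
        """All application years in which the compound was cited."""
        return frozenset(p.year for p in self.patents if p.year is not None)


def dedupe(occurrences: Iterable[CompoundOccurrence]) -> list[CompoundRecord]:
    """Collapse occurrences into one record per InChIKey.

    Patents and annotation sources are unioned; the representative SMILES is
    the first seen; ``first_year`` is the minimum application year.  The
    operation is idempotent and order-independent up to output ordering,
    which is fixed (sorted by InChIKey) for determinism.
    """
    grouped: dict[str, dict] = {}
    for occ in occurrences:
        slot = grouped.setdefault(
            occ.inchikey, {"smiles": occ.smiles, "patents": set(), "sections": set()}
        )
        slot["patents"].add(occ.patent)
        slot["sections"].update(occ.sections)
    records = []
    for key in sorted(grouped):
        slot = grouped[key]
        years = [p.year for p in slot["patents"] if p.year is not None]
        records.append(
            CompoundRecord(
                inchikey=key,
                smiles=slot["smiles"],
                patents=frozenset(slot["patents"]),
                sections=frozenset(slot["sections"]),
                first_year=min(years),
            )
        )
    return records


#: Promiscuity bins: singletons, 2-4, 5-1000, and the >1000 heavy tail.
PROMISCUITY_BINS = ("1", "2-4", "5-1000", ">1000")


@dataclass
class PromiscuityHistogram:
    """Compound-to-patent-count distribution over the standard bins."""

    bins: dict[str, int]
    counts: list[int]

    def to_dict(self) -> dict:
        return {"bins": dict(self.bins), "n_compounds": len(self.counts)}


def promiscuity_distribution(records: Sequence[CompoundRecord]) -> PromiscuityHistogram:
    """Bin compounds by how many distinct patent documents cite them.

    Bin edges follow the promiscuity thresholds of interest: fewer than 5
    documents versus more than 1,000 documents.
    """
    counts = [rec.n_patents for rec in records]
    bins = dict.fromkeys(PROMISCUITY_BINS, 0)
    for c in counts:
        if c == 1:
            bins["1"] += 1
        elif c <= 4:
            bins["2-4"] += 1
        elif c <= 1000:
            bins["5-1000"] += 1
        else:
            bins[">1000"] += 1
    return PromiscuityHistogram(bins=bins, counts=counts)


def kind_country_table(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Distinct-compound counts per (country, kind group).

    A compound counts toward every (country, kind group) combination its
    patent set touches, mirroring per-jurisdiction document-type summaries.
    """
    rows: dict[tuple[str, str], set[str]] = {}
    for rec in records:
        for p in rec.patents:
            rows.setdefault((p.country, kind_group(p.kind).value), set()).add(rec.inchikey)
    data = [
        {"country": c, "kind_group": g, "n_compounds": len(keys)}
        for (c, g), keys in sorted(rows.items())
    ]
    return pd.DataFrame(data, columns=["country", "kind_group", "n_compounds"])


def per_year_counts(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Distinct patents and newly-appearing compounds per application year."""
    patents: dict[int, set[str]] = {}
    compounds: dict[int, int] = {}
    for rec in records:
        compounds[rec.first_year] = compounds.get(rec.first_year, 0) + 1
        for p in rec.patents:
            if p.year is not None:
                patents.setdefault(p.year, set()).add(p.scpn)
    years = sorted(set(patents) | set(compounds))
    return pd.DataFrame(
        {
            "year": years,
            "n_patents": [len(patents.get(y, ())) for y in years],
            "n_new_compounds": [compounds.get(y, 0) for y in years],
        }
    )
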