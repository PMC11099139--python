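"""Desalting, descriptor panel and the Ro5 / bRo5 classifier."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from patentchem.druglikeness import (
    DescriptorVector,
    DruglikenessLabel,
    classify,
    compute_descriptors,
    desalt,
    label_shares,
    passes_bro5,
    passes_ro5,
    profile_records,
    top_prevalent,
    yearly_property_means,
)
from patentchem.errors import DesaltError, SmilesParseError
from patentchem.ingest import CompoundOccurrence, SectionSource, dedupe, parse_scpn

from exemplars import BRO5_EXEMPLARS, RO5_EXEMPLARS


def vector(**overrides):
    """A benign Ro5-passing descriptor vector to perturb in tests."""
    base = dict(mw=300.0, clogp=2.0, hba=3, hbd=1, tpsa=60.0, nrotb=4,
                n_rings=1, n_stereo=0)
    base.update(overrides)
    return DescriptorVector(**base)


class TestDesalt:
    def test_sodium_salt_keeps_organic_fragment(self):
        assert desalt("CC(=O)[O-].[Na+]") == "CC(=O)[O-]"

    def test_single_fragment_is_canonicalized(self):
        assert desalt("c1ccccc1") == Chem.CanonSmiles("c1ccccc1")

    def test_largest_organic_fragment_wins(self):
        # 6 heavy atoms vs 3 heavy atoms
        assert desalt("CCO.c1ccccc1") == Chem.CanonSmiles("c1ccccc1")

    def test_unparsable_smiles_raises(self):
        with pytest.raises(SmilesParseError):
            desalt("not-a-smiles")

    def test_all_inorganic_input_raises(self):
        with pytest.raises(DesaltError, match="organic"):
            desalt("[Na+].[Cl-]")


class TestDescriptors:
    def test_benzene_panel(self):
        d = compute_descriptors("c1ccccc1")
        assert (d.hba, d.hbd, d.tpsa, d.nrotb, d.n_rings, d.n_stereo) == (
            0, 0, 0.0, 0, 1, 0
        )

    def test_methanol_panel(self):
        d = compute_descriptors("CO")
        assert (d.hba, d.hbd, d.n_rings) == (1, 1, 0)

    def test_paclitaxel_against_formula_oracle(self):
        # C47H51NO14: MW 853.9; N+O count 15; donors = 3 OH + 1 amide NH
        d = compute_descriptors(BRO5_EXEMPLARS["paclitaxel"])
        assert d.mw == pytest.approx(853.92, abs=0.5)
        assert d.hba == 15
        assert d.hbd == 4

    def test_deterministic(self):
        smi = RO5_EXEMPLARS["arginine"]
        assert compute_descriptors(smi) == compute_descriptors(smi)


class TestRules:
    def test_benign_vector_passes_ro5(self):
        assert passes_ro5(vector())

    @pytest.mark.parametrize(
        "overrides",
        [
            {"mw": 501.0},
            {"clogp": 5.1},
            {"hbd": 6},
            {"hba": 11},
            {"tpsa": 140.0},
            {"nrotb": 12},
        ],
    )
    def test_single_violation_fails_ro5(self, overrides):
        assert not passes_ro5(vector(**overrides))

    def test_bro5_needs_mw_window_and_one_violation(self):
        assert passes_bro5(vector(mw=600.0, hbd=6))
        assert not passes_bro5(vector(mw=3000.0, hbd=6))  # strict upper bound
        assert not passes_bro5(vector(mw=500.0, hbd=6))  # strict lower bound
        assert not passes_bro5(vector(mw=600.0))  # no violation

    def test_classify_precedence(self):
        assert classify(vector()) is DruglikenessLabel.RO5
        assert classify(vector(mw=600.0, hbd=6)) is DruglikenessLabel.BRO5
        # fails clogp <= 5, and mw <= 500 keeps it out of bRo5
        assert classify(vector(mw=400.0, clogp=8.0)) is DruglikenessLabel.NEITHER


class TestExemplars:
    @pytest.mark.parametrize("name", sorted(RO5_EXEMPLARS))
    def test_small_natural_products_are_ro5(self, name):
        d = compute_descriptors(desalt(RO5_EXEMPLARS[name]))
        assert classify(d) is DruglikenessLabel.RO5

    @pytest.mark.parametrize("name", sorted(BRO5_EXEMPLARS))
    def test_large_drugs_are_bro5(self, name):
        d = compute_descriptors(desalt(BRO5_EXEMPLARS[name]))
        assert classify(d) is DruglikenessLabel.BRO5

    def test_doxorubicin_donor_count_drives_bro5(self):
        d = compute_descriptors(BRO5_EXEMPLARS["doxorubicin"])
        assert d.mw == pytest.approx(543.5, abs=0.5)
        assert d.hbd == 6


def toy_records():
    keys = ["AAAAAAAAAAAAAA-AAAAAAAAAA-N", "BBBBBBBBBBBBBB-AAAAAAAAAA-N",
            "CCCCCCCCCCCCCC-AAAAAAAAAA-N"]
    smiles = ["c1ccccc1", "Cc1ccccc1", "CCO"]
    occurrences = []
    for i, (key, smi) in enumerate(zip(keys, smiles)):
        for j in range(i + 1):
            occurrences.append(
                CompoundOccurrence(
                    schembl_id=f"SCHEMBL{i}",
                    smiles=smi,
                    inchikey=key,
                    patent=parse_scpn(f"US-{1111111 + 10 * i + j}-A1",
                                      year=2015 + i),
                    sections=frozenset({SectionSource.IMAGE}),
                )
            )
    return dedupe(occurrences)


class TestProfileTables:
    def test_yearly_means_match_groupby_oracle(self):
        profile = profile_records(toy_records())
        means = yearly_property_means(profile)
        oracle = (
            profile.groupby("first_year")[["mw", "clogp", "hba", "hbd",
                                           "nrotb", "n_rings", "n_stereo"]]
            .mean()
        )
        for row in means.itertuples():
            for prop in ("mw", "clogp", "hba", "hbd", "nrotb"):
                assert getattr(row, prop) == pytest.approx(
                    oracle.loc[row.year, prop], abs=1e-9
                )

    def test_single_compound_mean_is_itself(self):
        profile = profile_records(toy_records()[:1])
        means = yearly_property_means(profile)
        assert len(means) == 1
        assert means.loc[0, "mw"] == pytest.approx(profile.loc[0, "mw"])

    def test_two_compound_average(self):
        profile = pd.DataFrame(
            {
                "first_year": [2016, 2016],
                "mw": [400.0, 500.0],
                "clogp": [1.0, 2.0],
                "hba": [1, 3], "hbd": [0, 2], "nrotb": [2, 4],
                "n_rings": [1, 1], "n_stereo": [0, 0],
            }
        )
        means = yearly_property_means(profile)
        assert means.loc[0, "mw"] == pytest.approx(450.0)

    def test_label_shares_sum_to_100(self, small_corpus):
        _, paths, _ = small_corpus
        from patentchem.ingest import read_map_dump

        occurrences, _ = read_map_dump(paths.map_file)
        profile = profile_records(dedupe(occurrences))
        shares = label_shares(profile)
        assert sum(shares.values()) == pytest.approx(100.0)

    def test_top_prevalent_sorts_and_breaks_ties_by_key(self):
        profile = pd.DataFrame(
            {
                "inchikey": ["K3", "K1", "K2", "K4"],
                "label": ["ro5", "ro5", "ro5", "bro5"],
                "n_patents": [5, 9, 5, 2],
            }
        )
        top = top_prevalent(profile, DruglikenessLabel.RO5, 2)
        assert top == [("K1", 9), ("K2", 5)]
        # k larger than the pool returns the full pool
        assert len(top_prevalent(profile, DruglikenessLabel.BRO5, 5)) == 1


class TestMutualExclusivity:
    def test_random_vectors_never_satisfy_both(self):
        rng = np.random.default_rng(1234)
        n = 10_000
        mws = rng.uniform(50, 3500, n)
        # force boundary coverage
        mws[:4] = [500.0, 500.0, 3000.0, 2999.9]
        for i in range(n):
            d = DescriptorVector(
                mw=float(mws[i]),
                clogp=float(rng.uniform(-5, 12)),
                hba=int(rng.integers(0, 25)),
                hbd=int(rng.integers(0, 15)),
                tpsa=float(rng.uniform(0, 400)),
                nrotb=int(rng.integers(0, 35)),
                n_rings=int(rng.integers(0, 10)),
                n_stereo=int(rng.integers(0, 10)),
            )
            assert not (passes_ro5(d) and passes_bro5(d))
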