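"""Drug-likeness profiling: desalting, descriptors, Ro5 / bRo5 labels.

The classifier applies two published frameworks:

* extended Rule of Five (Ro5): MW <= 500, cLogP <= 5, HBD <= 5, HBA <= 10,
  plus the Veber oral-bioavailability criteria TPSA < 140 and NRotB < 12;
* beyond-Ro5 (bRo5): 500 < MW < 3000 Da with at least one property past the
  extended-Ro5 bounds (cLogP > 7.5 or < 0, HBD > 5, HBA > 10, TPSA > 200,
  NRotB > 20).

Hydrogen-bond counts use the classic Lipinski conventions: HBA is the N+O
atom count, HBD the NH/OH donor-atom count.  LogP is the Wildman-Crippen
atomic-contribution estimate and TPSA the Ertl fragment sum.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .errors import DesaltError, DescriptorError, SmilesParseError
from .ingest import CompoundRecord

logger = logging.getLogger(__name__)


class DruglikenessLabel(enum.Enum):
    RO5 = "ro5"
    BRO5 = "bro5"
    NEITHER = "neither"


@dataclass(frozen=True)
class DescriptorVector:
    """The physicochemical profile of one desalted structure."""

    mw: float
    clogp: float
    hba: int
    hbd: int
    tpsa: float
    nrotb: int
    n_rings: int
    n_stereo: int


@dataclass(frozen=True)
class RuleSet:
    """Thresholds of the extended-Ro5 and bRo5 frameworks.

    Defaults are the published values; any override is logged so deviations
    from the standard frameworks are visible in run logs.
    """

    ro5_mw_max: float = 500.0
    ro5_clogp_max: float = 5.0
    ro5_hbd_max: int = 5
    ro5_hba_max: int = 10
    veber_tpsa_max: float = 140.0  # strict <
    veber_nrotb_max: int = 12  # strict <
    bro5_mw_min: float = 500.0  # strict >
    bro5_mw_max: float = 3000.0  # strict <
    bro5_clogp_high: float = 7.5  # violation when >
    bro5_clogp_low: float = 0.0  # violation when <
    bro5_hbd: int = 5  # violation when >
    bro5_hba: int = 10  # violation when >
    bro5_tpsa: float = 200.0  # violation when >
    bro5_nrotb: int = 20  # violation when >

    def override(self, **kwargs) -> "RuleSet":
        logger.warning("rule-set thresholds overridden: %s", kwargs)
        return replace(self, **kwargs)


DEFAULT_RULES = RuleSet()


def _mol_from_smiles(smiles: str, context: str = "") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, context)
    return mol


def desalt(smiles: str) -> str:
    """Keep the main organic fragment of a (possibly multi-fragment) SMILES.

    Among carbon-containing fragments the one with most heavy atoms wins;
    ties break toward higher molecular weight, then the lexicographically
    smallest canonical SMILES.  Single-fragment input is returned in
    canonical form.  No neutralization or tautomer canonicalization is
    attempted.
    """
    mol = _mol_from_smiles(smiles, "desalt")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    organic = [
        f for f in frags if any(a.GetSymbol() == "C" for a in f.GetAtoms())
    ]
    if not organic:
        raise DesaltError(f"no organic fragment in {smiles!r}")
    best = max(
        organic,
        key=lambda f: (
            f.GetNumHeavyAtoms(),
            Descriptors.MolWt(f),
            # invert for lexicographically *smallest* SMILES on full tie
            tuple(-ord(ch) for ch in Chem.MolToSmiles(f)),
        ),
    )
    return Chem.MolToSmiles(best)


def compute_descriptors(smiles: str) -> DescriptorVector:
    """Compute the descriptor panel for a desalted, valid SMILES."""
    mol = _mol_from_smiles(smiles, "descriptors")
    try:
        return DescriptorVector(
            mw=Descriptors.MolWt(mol),
            clogp=Crippen.MolLogP(mol),
            hba=Lipinski.NOCount(mol),
            hbd=Lipinski.NumHDonors(mol),
            tpsa=rdMolDescriptors.CalcTPSA(mol),
            nrotb=Lipinski.NumRotatableBonds(mol),
            n_rings=rdMolDescriptors.CalcNumRings(mol),
            n_stereo=len(
                Chem.FindMolChiralCenters(
                    mol, includeUnassigned=True, useLegacyImplementation=False
                )
            ),
        )
    except SmilesParseError:
        raise
    except Exception as exc:  # pragma: no cover - backend failure path
        raise DescriptorError("descriptor-panel", smiles, str(exc)) from exc


def passes_ro5(d: DescriptorVector, rules: RuleSet = DEFAULT_RULES) -> bool:
    """Strict-conjunction extended Ro5: zero violations tolerated."""
    return (
        d.mw <= rules.ro5_mw_max
        and d.clogp <= rules.ro5_clogp_max
        and d.hbd <= rules.ro5_hbd_max
        and d.hba <= rules.ro5_hba_max
        and d.tpsa < rules.veber_tpsa_max
        and d.nrotb < rules.veber_nrotb_max
    )


def passes_bro5(d: DescriptorVector, rules: RuleSet = DEFAULT_RULES) -> bool:
    """500 < MW < 3000 with >= 1 property beyond the extended-Ro5 bounds."""
    if not (rules.bro5_mw_min < d.mw < rules.bro5_mw_max):
        return False
    return (
        d.clogp > rules.bro5_clogp_high
        or d.clogp < rules.bro5_clogp_low
        or d.hbd > rules.bro5_hbd
        or d.hba > rules.bro5_hba
        or d.tpsa > rules.bro5_tpsa
        or d.nrotb > rules.bro5_nrotb
    )


def classify(d: DescriptorVector, rules: RuleSet = DEFAULT_RULES) -> DruglikenessLabel:
    """Assign RO5, else BRO5, else NEITHER (total and deterministic)."""
    if passes_ro5(d, rules):
        return DruglikenessLabel.RO5
    if passes_bro5(d, rules):
        return DruglikenessLabel.BRO5
    return DruglikenessLabel.NEITHER


#: Columns of the Table-2-style yearly mean panel (TPSA is a rule input but
#: not part of the published yearly panel).
YEARLY_MEAN_PROPERTIES = ("mw", "clogp", "hba", "hbd", "nrotb", "n_rings", "n_stereo")


def profile_records(
    records: Sequence[CompoundRecord], rules: RuleSet = DEFAULT_RULES
) -> pd.DataFrame:
    """Desalt, describe and classify a deduplicated compound table.

    Returns one row per compound: InChIKey, desalted SMILES, the descriptor
    panel, the drug-likeness label, patent count and first application year.
    Rows are sorted by InChIKey for run-to-run determinism.
    """
    rows = []
    for rec in sorted(records, key=lambda r: r.inchikey):
        parent = desalt(rec.smiles)
        d = compute_descriptors(parent)
        rows.append(
            {
                "inchikey": rec.inchikey,
                "smiles": parent,
                "mw": d.mw,
                "clogp": d.clogp,
                "hba": d.hba,
                "hbd": d.hbd,
                "tpsa": d.tpsa,
                "nrotb": d.nrotb,
                "n_rings": d.n_rings,
                "n_stereo": d.n_stereo,
                "label": classify(d, rules).value,
                "n_patents": rec.n_patents,
                "first_year": rec.first_year,
            }
        )
    columns = [
        "inchikey", "smiles", "mw", "clogp", "hba", "hbd", "tpsa", "nrotb",
        "n_rings", "n_stereo", "label", "n_patents", "first_year",
    ]
    return pd.DataFrame(rows, columns=columns)


def label_shares(profile: pd.DataFrame) -> dict[str, float]:
    """Percentage of compounds per drug-likeness label (sums to 100)."""
    n = len(profile)
    shares = {label.value: 0.0 for label in DruglikenessLabel}
    if n == 0:
        return shares
    for label, count in profile["label"].value_counts().items():
        shares[str(label)] = 100.0 * count / n
    return shares


def yearly_property_means(profile: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic per-year means of the seven-property panel.

    Years with zero compounds are omitted (and logged).  Means are never
    rounded here; rounding is a serialization concern.
    """
    if profile.empty:
        return pd.DataFrame(columns=["year", *YEARLY_MEAN_PROPERTIES])
    grouped = (
        profile.groupby("first_year")[list(YEARLY_MEAN_PROPERTIES)]
        .mean()
        .reset_index()
        .rename(columns={"first_year": "year"})
        .sort_values("year", ignore_index=True)
    )
    return grouped


def top_prevalent(
    profile: pd.DataFrame, label: DruglikenessLabel, k: int
) -> list[tuple[str, int]]:
    """The k compounds of a label with the largest patent counts.

    Ties break by InChIKey lexicographic order.  When fewer than k
    compounds carry the label the full (shorter) list is returned.
    """
    pool = profile[profile["label"] == label.value]
    if len(pool) < k:
        logger.info(
            "only %d compounds labelled %s (k=%d)", len(pool), label.value, k
        )
    ranked = pool.sort_values(
        ["n_patents", "inchikey"], ascending=[False, True], ignore_index=True
    )
    return [
        (row.inchikey, int(row.n_patents)) for row in ranked.head(k).itertuples()
    ]
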