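"""Bemis-Murcko scaffold reduction and scaffold-level summaries.

A Bemis-Murcko scaffold is a molecule's ring systems plus the linkers that
connect them, with all side chains pruned; heteroatoms and bond orders are
retained (this is the heteroatom-retaining scaffold, deliberately not the
carbon-skeleton "graph framework").  Acyclic molecules have no scaffold and
are tallied separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from .druglikeness import desalt
from .errors import SmilesParseError
from .ingest import CompoundRecord, SectionSource

logger = logging.getLogger(__name__)


def bm_scaffold(smiles: str) -> str:
    """Canonical SMILES of the Bemis-Murcko scaffold; empty if acyclic.

    Idempotent: the scaffold of a scaffold is itself.  The scaffold's heavy
    atom count and weight never exceed the parent's.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, "bm_scaffold")
    if mol.GetRingInfo().NumRings() == 0:
        return ""
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


@dataclass(frozen=True)
class ScaffoldRecord:
    """One distinct scaffold with its parent-compound aggregates."""

    scaffold_smiles: str
    mw: float
    first_year: int
    frequency: int
    sections: frozenset[SectionSource]
    years: frozenset[int]


@dataclass
class ScaffoldTable:
    """All distinct scaffolds of a corpus plus the acyclic-parent tally."""

    records: list[ScaffoldRecord]
    n_acyclic_parents: int

    def __len__(self) -> int:
        return len(self.records)


def scaffold_table(
    records: Sequence[CompoundRecord],
    smiles_by_key: Mapping[str, str] | None = None,
) -> ScaffoldTable:
    """Group deduplicated compounds by their Bemis-Murcko scaffold.

    ``smiles_by_key`` may supply pre-desalted SMILES per InChIKey (as the
    profiling stage produces); otherwise each record's SMILES is desalted
    here.  Frequency counts parent compounds; first_year, citation years and
    annotation sources are aggregated over parents.  Acyclic parents carry
    no scaffold and are only counted.
    """
    grouped: dict[str, dict] = {}
    n_acyclic = 0
    for rec in sorted(records, key=lambda r: r.inchikey):
        smiles = (
            smiles_by_key[rec.inchikey] if smiles_by_key is not None else desalt(rec.smiles)
        )
        scaffold = bm_scaffold(smiles)
        if scaffold == "":
            n_acyclic += 1
            continue
        slot = grouped.setdefault(
            scaffold,
            {"frequency": 0, "first_year": rec.first_year, "sections": set(), "years": set()},
        )
        slot["frequency"] += 1
        slot["first_year"] = min(slot["first_year"], rec.first_year)
        slot["sections"].update(rec.sections)
        slot["years"].update(rec.years)
    out = []
    for smiles in sorted(grouped):
        slot = grouped[smiles]
        out.append(
            ScaffoldRecord(
                scaffold_smiles=smiles,
                mw=Descriptors.MolWt(Chem.MolFromSmiles(smiles)),
                first_year=slot["first_year"],
                frequency=slot["frequency"],
                sections=frozenset(slot["sections"]),
                years=frozenset(slot["years"]),
            )
        )
    return ScaffoldTable(records=out, n_acyclic_parents=n_acyclic)


def novelty_by_year(table: ScaffoldTable) -> pd.DataFrame:
    """Per-year counts of new versus known scaffolds.

    A scaffold is "new" in the first year it is cited within the loaded
    corpus and "known" in every later year it recurs, mirroring the
    comparison of scaffold SMILES against previous years.  New counts sum
    to the number of distinct scaffolds.
    """
    new: dict[int, int] = {}
    known: dict[int, int] = {}
    for rec in table.records:
        first = min(rec.years) if rec.years else rec.first_year
        new[first] = new.get(first, 0) + 1
        for year in rec.years:
            if year > first:
                known[year] = known.get(year, 0) + 1
    years = sorted(set(new) | set(known))
    return pd.DataFrame(
        {
            "year": years,
            "new": [new.get(y, 0) for y in years],
            "known": [known.get(y, 0) for y in years],
        }
    )


def scaffold_section_attribution(table: ScaffoldTable) -> pd.DataFrame:
    """Distinct-scaffold counts (and percentages) per annotation source.

    A scaffold counts toward every source its parents were annotated from,
    so the percentages over distinct scaffolds may jointly exceed 100; the
    share over scaffold-section pairs (which sums to 100) is reported
    alongside.
    """
    counts = {s: 0 for s in SectionSource}
    for rec in table.records:
        for s in rec.sections:
            counts[s] += 1
    n_scaffolds = len(table.records)
    n_pairs = sum(counts.values())
    rows = [
        {
            "section": s.value,
            "n_scaffolds": counts[s],
            "pct_of_scaffolds": 100.0 * counts[s] / n_scaffolds if n_scaffolds else 0.0,
            "pct_of_pairs": 100.0 * counts[s] / n_pairs if n_pairs else 0.0,
        }
        for s in SectionSource
    ]
    return pd.DataFrame(rows)


def mw_distribution(table: ScaffoldTable) -> dict[str, float]:
    """Min / quartiles / max of the scaffold molecular-weight distribution."""
    if not table.records:
        return {"min": 0.0, "q25": 0.0, "median": 0.0, "q75": 0.0, "max": 0.0}
    mws = np.array([rec.mw for rec in table.records])
    q25, med, q75 = np.percentile(mws, [25, 50, 75])
    return {
        "min": float(mws.min()),
        "q25": float(q25),
        "median": float(med),
        "q75": float(q75),
        "max": float(mws.max()),
    }


def top_scaffolds(table: ScaffoldTable, k: int) -> list[dict]:
    """The k most frequent scaffolds (ties by scaffold SMILES order)."""
    ranked = sorted(table.records, key=lambda r: (-r.frequency, r.scaffold_smiles))
    if k > len(ranked):
        logger.info("k=%d exceeds scaffold count %d; returning all", k, len(ranked))
    return [
        {"scaffold": r.scaffold_smiles, "frequency": r.frequency, "mw": r.mw}
        for r in ranked[: max(k, 0)]
    ]
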