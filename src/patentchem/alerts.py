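"""PAINS substructure screening.

Pan-Assay INterference Structures (PAINS) are substructure patterns that
flag compounds prone to nonspecific assay interference.  The built-in
catalog is the published three-family set (A: 16, B: 55, C: 409 patterns)
as compiled in RDKit's FilterCatalog; user-supplied two-column SMARTS files
are also accepted.  Matching operates on the desalted parent structure with
aromaticity perceived; one compound may trigger many alerts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import FilterCatalog
from rdkit.Chem.FilterCatalog import FilterCatalogParams

from .errors import CatalogError, SmilesParseError

logger = logging.getLogger(__name__)

_PAINS_FAMILIES = {
    "A": FilterCatalogParams.FilterCatalogs.PAINS_A,
    "B": FilterCatalogParams.FilterCatalogs.PAINS_B,
    "C": FilterCatalogParams.FilterCatalogs.PAINS_C,
}


@dataclass(frozen=True)
class AlertDefinition:
    """One named substructure alert.

    ``smarts`` is populated for user-supplied patterns; catalog entries
    carry their pre-compiled matcher instead.
    """

    name: str
    family: str
    smarts: str | None = None
    _entry: object = field(default=None, compare=False, repr=False)
    _pattern: object = field(default=None, compare=False, repr=False)

    def matches(self, mol: Chem.Mol) -> bool:
        if self._entry is not None:
            return self._entry.HasFilterMatch(mol)
        return mol.HasSubstructMatch(self._pattern)


@dataclass(frozen=True)
class AlertHit:
    inchikey: str
    alert: str


def load_catalog(name: str | Path = "pains") -> list[AlertDefinition]:
    """Load the built-in PAINS catalog or a user SMARTS file.

    ``name="pains"`` yields the full A+B+C family set in deterministic
    (family, catalog) order.  Any other value is treated as a path to a
    tab-separated two-column file (alert name, SMARTS); an uncompilable
    pattern raises :class:`CatalogError` naming the offending line.
    """
    if isinstance(name, str) and name.lower() == "pains":
        defs: list[AlertDefinition] = []
        for family, fam_enum in _PAINS_FAMILIES.items():
            params = FilterCatalogParams()
            params.AddCatalog(fam_enum)
            catalog = FilterCatalog.FilterCatalog(params)
            for i in range(catalog.GetNumEntries()):
                entry = catalog.GetEntryWithIdx(i)
                defs.append(
                    AlertDefinition(
                        name=entry.GetDescription(), family=family, _entry=entry
                    )
                )
        if not defs:  # pragma: no cover - would indicate a broken install
            raise CatalogError("built-in PAINS catalog is empty")
        logger.info("loaded built-in PAINS catalog: %d patterns", len(defs))
        return defs

    path = Path(name)
    if not path.exists():
        raise CatalogError(f"alert catalog not found: {path}")
    defs = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CatalogError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            alert_name, smarts = parts[0].strip(), parts[1].strip()
            if alert_name in seen:
                raise CatalogError(f"{path}:{lineno}: duplicate alert {alert_name!r}")
            pattern = Chem.MolFromSmarts(smarts)
            if pattern is None:
                raise CatalogError(
                    f"{path}:{lineno}: SMARTS for {alert_name!r} does not compile"
                )
            seen.add(alert_name)
            defs.append(
                AlertDefinition(
                    name=alert_name, family="user", smarts=smarts, _pattern=pattern
                )
            )
    if not defs:
        raise CatalogError(f"alert catalog {path} contains no patterns")
    logger.info("loaded user catalog %s: %d patterns", path, len(defs))
    return defs


def screen(smiles: str, catalog: Sequence[AlertDefinition], inchikey: str = "") -> list[AlertHit]:
    """All alerts matched by one desalted structure (deterministic order)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, "screen")
    return [AlertHit(inchikey=inchikey, alert=d.name) for d in catalog if d.matches(mol)]


@dataclass
class AlertSummary:
    """Corpus-level screening statistics."""

    per_alert: dict[str, int]
    n_alerts_hit: int
    n_flagged: int
    n_compounds: int
    hits: pd.DataFrame

    @property
    def flagged_fraction(self) -> float:
        return self.n_flagged / self.n_compounds if self.n_compounds else 0.0

    def to_dict(self) -> dict:
        return {
            "n_compounds": self.n_compounds,
            "n_flagged": self.n_flagged,
            "flagged_fraction": self.flagged_fraction,
            "n_alerts_hit": self.n_alerts_hit,
            "per_alert": dict(sorted(self.per_alert.items())),
        }


def alert_summary(
    compounds: Iterable[tuple[str, str]], catalog: Sequence[AlertDefinition]
) -> AlertSummary:
    """Screen (inchikey, desalted SMILES) pairs and aggregate.

    Per-alert counts are distinct compounds, never occurrences; the flagged
    fraction is the share of compounds with at least one hit.
    """
    per_alert_keys: dict[str, set[str]] = {}
    flagged: set[str] = set()
    rows = []
    seen: set[str] = set()
    for inchikey, smiles in compounds:
        if inchikey in seen:  # defensive: summary counts distinct compounds
            continue
        seen.add(inchikey)
        for hit in screen(smiles, catalog, inchikey=inchikey):
            per_alert_keys.setdefault(hit.alert, set()).add(inchikey)
            flagged.add(inchikey)
            rows.append({"inchikey": inchikey, "alert": hit.alert})
    hits = pd.DataFrame(rows, columns=["inchikey", "alert"])
    return AlertSummary(
        per_alert={name: len(keys) for name, keys in per_alert_keys.items()},
        n_alerts_hit=len(per_alert_keys),
        n_flagged=len(flagged),
        n_compounds=len(seen),
        hits=hits,
    )
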