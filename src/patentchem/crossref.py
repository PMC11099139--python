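"""Cross-database mapping of patent compounds by exact InChIKey match.

Compounds are considered the same across resources only when the full
27-character InChIKey matches exactly — stereoisomers therefore do not
cross-match (no connectivity-block matching).  Resources are plain
tab-separated files (InChIKey plus optional clinical annotations), keeping
the stage deterministic and network-free.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import IngestError
from .ingest import INCHIKEY_RE, CompoundRecord

logger = logging.getLogger(__name__)


class MaxPhase(enum.Enum):
    """Furthest clinical development stage reached by a compound."""

    UNKNOWN = "unknown"
    PRECLINICAL = "preclinical"
    PHASE1 = "phase1"
    PHASE2 = "phase2"
    PHASE3 = "phase3"
    APPROVED = "approved"


class ApprovalStatus(enum.Enum):
    INVESTIGATIONAL = "investigational"
    WITHDRAWN = "withdrawn"
    APPROVED = "approved"


#: Numeric max-phase vocabulary mapping.  Resources encode phases as
#: integers; the boundary between "preclinical" and "unknown" is not
#: universal, so the table is explicit and overridable rather than
#: hard-coded into the matching logic.
DEFAULT_PHASE_MAP: Mapping[int, MaxPhase] = {
    -1: MaxPhase.UNKNOWN,
    0: MaxPhase.PRECLINICAL,
    1: MaxPhase.PHASE1,
    2: MaxPhase.PHASE2,
    3: MaxPhase.PHASE3,
    4: MaxPhase.APPROVED,
}


@dataclass(frozen=True)
class ClinicalAnnotation:
    max_phase: MaxPhase = MaxPhase.UNKNOWN
    status: ApprovalStatus | None = None


@dataclass
class ResourceTable:
    """An external compound resource keyed by InChIKey."""

    name: str
    keys: frozenset[str]
    annotations: dict[str, ClinicalAnnotation] = field(default_factory=dict)


def load_resource(
    name: str,
    path: str | Path,
    phase_map: Mapping[int, MaxPhase] = DEFAULT_PHASE_MAP,
) -> ResourceTable:
    """Read a resource TSV with columns inchikey[, max_phase][, status].

    Rows with a malformed InChIKey are dropped with a warning, never
    repaired.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"resource file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "inchikey" not in df.columns:
        raise IngestError(f"resource file {path} lacks an 'inchikey' column")
    keys = set()
    annotations = {}
    n_dropped = 0
    for row in df.itertuples(index=False):
        key = row.inchikey.strip()
        if not INCHIKEY_RE.match(key):
            n_dropped += 1
            continue
        keys.add(key)
        phase = None
        if "max_phase" in df.columns and str(getattr(row, "max_phase", "")).strip():
            phase = phase_map.get(int(str(row.max_phase).strip()), MaxPhase.UNKNOWN)
        status = None
        if "status" in df.columns and str(getattr(row, "status", "")).strip():
            status = ApprovalStatus(str(row.status).strip().lower())
        if phase is not None or status is not None:
            annotations[key] = ClinicalAnnotation(
                max_phase=phase if phase is not None else MaxPhase.UNKNOWN,
                status=status,
            )
    if n_dropped:
        logger.warning("resource %s: dropped %d malformed InChIKey rows", name, n_dropped)
    return ResourceTable(name=name, keys=frozenset(keys), annotations=annotations)


def match_by_inchikey(
    records: Sequence[CompoundRecord], resource: ResourceTable
) -> pd.Series:
    """Boolean membership per compound (indexed by InChIKey, sorted)."""
    keys = sorted(rec.inchikey for rec in records)
    return pd.Series(
        [k in resource.keys for k in keys], index=keys, name=resource.name
    )


def overlap_summary(
    records: Sequence[CompoundRecord], resources: Sequence[ResourceTable]
) -> dict[str, int]:
    """Counts of every membership combination (Euler regions).

    Region keys are '+'-joined sorted resource names; compounds found in no
    resource fall under ``"none"``.  Region counts always sum to the number
    of compounds.
    """
    region_counts: dict[str, int] = {}
    for rec in records:
        members = sorted(r.name for r in resources if rec.inchikey in r.keys)
        key = "+".join(members) if members else "none"
        region_counts[key] = region_counts.get(key, 0) + 1
    return dict(sorted(region_counts.items()))


def exclusive_set(
    records: Sequence[CompoundRecord], resources: Sequence[ResourceTable]
) -> tuple[list[str], pd.DataFrame]:
    """Compounds found in none of the resources, with a per-year trend.

    The exclusive set and the matched-in-any set partition the corpus.
    """
    exclusive = sorted(
        rec.inchikey
        for rec in records
        if not any(rec.inchikey in r.keys for r in resources)
    )
    keyset = set(exclusive)
    per_year: dict[int, int] = {}
    for rec in records:
        if rec.inchikey in keyset:
            per_year[rec.first_year] = per_year.get(rec.first_year, 0) + 1
    years = sorted(per_year)
    trend = pd.DataFrame(
        {"year": years, "n_exclusive": [per_year[y] for y in years]}
    )
    return exclusive, trend


@dataclass
class ClinicalSummary:
    """Phase distribution and approval-status counts for a corpus."""

    phase_counts: dict[str, int]
    status_counts: dict[str, int]
    n_matched: int
    n_unmatched: int
    conflicts: list[str]

    def to_dict(self) -> dict:
        return {
            "phase_counts": dict(sorted(self.phase_counts.items())),
            "status_counts": dict(sorted(self.status_counts.items())),
            "n_matched": self.n_matched,
            "n_unmatched": self.n_unmatched,
            "n_conflicts": len(self.conflicts),
            "conflicts": list(self.conflicts),
        }


def annotate_clinical(
    records: Sequence[CompoundRecord],
    chembl_like: ResourceTable,
    drugbank_like: ResourceTable,
) -> ClinicalSummary:
    """Assign each matched compound its max phase and approval status.

    Compounds matched in the phase resource without an annotation fall in
    the UNKNOWN bucket.  A compound annotated APPROVED by phase but
    WITHDRAWN by status (or vice versa) is counted in both tables and
    flagged as a conflict rather than silently resolved.
    """
    phase_counts = {p.value: 0 for p in MaxPhase}
    status_counts = {s.value: 0 for s in ApprovalStatus}
    conflicts = []
    n_matched = 0
    for rec in sorted(records, key=lambda r: r.inchikey):
        in_chembl = rec.inchikey in chembl_like.keys
        in_drugbank = rec.inchikey in drugbank_like.keys
        phase = None
        if in_chembl:
            n_matched += 1
            ann = chembl_like.annotations.get(rec.inchikey)
            phase = ann.max_phase if ann is not None else MaxPhase.UNKNOWN
            phase_counts[phase.value] += 1
        if in_drugbank:
            ann = drugbank_like.annotations.get(rec.inchikey)
            if ann is not None and ann.status is not None:
                status_counts[ann.status.value] += 1
                approved_vs_withdrawn = (
                    phase is MaxPhase.APPROVED
                    and ann.status is ApprovalStatus.WITHDRAWN
                ) or (
                    phase is not None
                    and phase is not MaxPhase.APPROVED
                    and phase is not MaxPhase.UNKNOWN
                    and ann.status is ApprovalStatus.APPROVED
                )
                if approved_vs_withdrawn:
                    conflicts.append(rec.inchikey)
    return ClinicalSummary(
        phase_counts=phase_counts,
        status_counts=status_counts,
        n_matched=n_matched,
        n_unmatched=len(records) - n_matched,
        conflicts=conflicts,
    )
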