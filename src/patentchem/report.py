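"""Full-pipeline orchestration and the summary bundle.

``run_pipeline`` chains ingest -> desalt/descriptors/classification ->
scaffolds -> PAINS screening -> cross-referencing and aggregates every
stage into one :class:`ReportBundle` of plain numbers (counts, shares,
rankings).  The bundle serializes to JSON/CSV; percentages are rounded
only at serialization time (2 decimals), never internally.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .alerts import load_catalog, alert_summary
from .crossref import (
    ResourceTable,
    annotate_clinical,
    exclusive_set,
    load_resource,
    overlap_summary,
)
from .druglikeness import (
    DruglikenessLabel,
    label_shares,
    profile_records,
    top_prevalent,
    yearly_property_means,
)
from .errors import PatentChemError
from .ingest import (
    ColumnMap,
    CompoundRecord,
    dedupe,
    kind_country_table,
    per_year_counts,
    promiscuity_distribution,
    read_map_dump,
)
from .scaffolds import (
    mw_distribution,
    novelty_by_year,
    scaffold_section_attribution,
    scaffold_table,
    top_scaffolds,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and knobs of one pipeline run."""

    map_file: str | Path
    resource_files: Mapping[str, str | Path] = field(default_factory=dict)
    min_year: int | None = 2015
    top_k: int = 10
    catalog: str = "pains"
    column_map: ColumnMap = field(default_factory=ColumnMap)

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "map_file": str(self.map_file),
                "resource_files": {k: str(v) for k, v in sorted(self.resource_files.items())},
                "min_year": self.min_year,
                "top_k": self.top_k,
                "catalog": self.catalog,
                "column_map": vars(self.column_map),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Every summary table of one run, as plain dict/list payloads."""

    load_report: dict
    n_compounds: int
    per_year: list[dict]
    kind_country: list[dict]
    promiscuity: dict
    section_shares: dict
    label_shares: dict
    top_prevalent: dict
    yearly_means: list[dict]
    pains: dict
    scaffolds: dict
    overlap_regions: dict
    exclusive: dict
    clinical: dict
    metadata: dict

    def to_dict(self) -> dict:
        return {
            "load_report": self.load_report,
            "n_compounds": self.n_compounds,
            "per_year": self.per_year,
            "kind_country": self.kind_country,
            "promiscuity": self.promiscuity,
            "section_shares": self.section_shares,
            "label_shares": self.label_shares,
            "top_prevalent": self.top_prevalent,
            "yearly_means": self.yearly_means,
            "pains": self.pains,
            "scaffolds": self.scaffolds,
            "overlap_regions": self.overlap_regions,
            "exclusive": self.exclusive,
            "clinical": self.clinical,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path, round_pct: int = 2) -> None:
        """Write the bundle; percentage fields rounded to ``round_pct``."""
        payload = _round_floats(self.to_dict(), round_pct)
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="\n") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _round_floats(obj, ndigits: int):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def section_annotation_shares(records: Sequence[CompoundRecord]) -> dict:
    """Per-source compound shares plus the multi-source share.

    A compound counts toward every source it was annotated from, so the
    per-source shares may jointly exceed 100%; the multi-source share is
    the fraction of compounds seen in two or more of the six sources.
    """
    from .ingest import SectionSource

    n = len(records)
    counts = {s.value: 0 for s in SectionSource}
    multi = 0
    for rec in records:
        for s in rec.sections:
            counts[s.value] += 1
        if len(rec.sections) >= 2:
            multi += 1
    return {
        "per_source_pct": {
            s: (100.0 * c / n if n else 0.0) for s, c in counts.items()
        },
        "per_source_count": counts,
        "multi_source_pct": 100.0 * multi / n if n else 0.0,
        "multi_source_count": multi,
    }


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and aggregate the bundle.

    A failure in any stage aborts with the stage name attached; stage
    timings and drop counts go to the log.
    """
    stage = "ingest"
    timings: dict[str, float] = {}
    try:
        t0 = time.perf_counter()
        occurrences, load_report = read_map_dump(
            config.map_file, config.column_map, min_year=config.min_year
        )
        records = dedupe(occurrences)
        promiscuity = promiscuity_distribution(records)
        timings[stage] = time.perf_counter() - t0

        stage = "profile"
        t0 = time.perf_counter()
        profile = profile_records(records)
        shares = label_shares(profile)
        means = yearly_property_means(profile)
        tops = {
            label.value: [
                {"inchikey": k, "n_patents": c}
                for k, c in top_prevalent(profile, label, config.top_k)
            ]
            for label in (DruglikenessLabel.RO5, DruglikenessLabel.BRO5)
        }
        timings[stage] = time.perf_counter() - t0

        stage = "scaffolds"
        t0 = time.perf_counter()
        smiles_by_key = dict(zip(profile["inchikey"], profile["smiles"]))
        table = scaffold_table(records, smiles_by_key=smiles_by_key)
        novelty = novelty_by_year(table)
        attribution = scaffold_section_attribution(table)
        scaffold_payload = {
            "n_scaffolds": len(table),
            "n_acyclic_parents": table.n_acyclic_parents,
            "mw_distribution": mw_distribution(table),
            "novelty_by_year": novelty.to_dict(orient="records"),
            "top_scaffolds": top_scaffolds(table, config.top_k),
            "section_attribution": attribution.to_dict(orient="records"),
        }
        timings[stage] = time.perf_counter() - t0

        stage = "alerts"
        t0 = time.perf_counter()
        catalog = load_catalog(config.catalog)
        pains = alert_summary(
            zip(profile["inchikey"], profile["smiles"]), catalog
        )
        pains_payload = pains.to_dict()
        pains_payload["flagged_pct"] = 100.0 * pains.flagged_fraction
        timings[stage] = time.perf_counter() - t0

        stage = "crossref"
        t0 = time.perf_counter()
        resources = [
            load_resource(name, path)
            for name, path in sorted(config.resource_files.items())
        ]
        regions = overlap_summary(records, resources)
        exclusive_keys, exclusive_trend = exclusive_set(records, resources)
        by_name = {r.name: r for r in resources}
        empty = ResourceTable(name="empty", keys=frozenset())
        clinical = annotate_clinical(
            records,
            by_name.get("chembl", empty),
            by_name.get("drugbank", empty),
        )
        timings[stage] = time.perf_counter() - t0

        stage = "aggregate"
        bundle = ReportBundle(
            load_report=load_report.to_dict(),
            n_compounds=len(records),
            per_year=per_year_counts(records).to_dict(orient="records"),
            kind_country=kind_country_table(records).to_dict(orient="records"),
            promiscuity=promiscuity.to_dict(),
            section_shares=section_annotation_shares(records),
            label_shares=shares,
            top_prevalent=tops,
            yearly_means=means.to_dict(orient="records"),
            pains=pains_payload,
            scaffolds=scaffold_payload,
            overlap_regions=regions,
            exclusive={
                "count": len(exclusive_keys),
                "pct": 100.0 * len(exclusive_keys) / len(records) if records else 0.0,
                "per_year": exclusive_trend.to_dict(orient="records"),
            },
            clinical=clinical.to_dict(),
            metadata={
                "config_hash": config.content_hash(),
                "package_version": __version__,
                "n_resources": len(resources),
            },
        )
    except PatentChemError as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise PatentChemError(f"stage {stage!r} failed: {exc}") from exc

    logger.info(
        "pipeline done: %s",
        ", ".join(f"{k}={v:.2f}s" for k, v in timings.items()),
    )
    return bundle
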