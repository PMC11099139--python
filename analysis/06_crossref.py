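#!/usr/bin/env python
"""Cross-reference compounds into the external resources by InChIKey.

Writes the Euler region counts, the exclusive-set trend and the clinical
phase / approval-status distributions.
"""

import json

from _common import ensure_corpus, results_dir

from patentchem.crossref import (
    annotate_clinical,
    exclusive_set,
    load_resource,
    overlap_summary,
)
from patentchem.ingest import dedupe, read_map_dump

paths = ensure_corpus()
out = results_dir()

occurrences, _ = read_map_dump(paths.map_file)
records = dedupe(occurrences)
resources = [
    load_resource(name, path) for name, path in sorted(paths.resource_files.items())
]

regions = overlap_summary(records, resources)
exclusive, trend = exclusive_set(records, resources)
by_name = {r.name: r for r in resources}
clinical = annotate_clinical(records, by_name["chembl"], by_name["drugbank"])

(out / "overlap_regions.json").write_text(json.dumps(regions, indent=2) + "\n")
trend.to_csv(out / "exclusive_trend.csv", index=False)
(out / "clinical.json").write_text(json.dumps(clinical.to_dict(), indent=2) + "\n")

n = len(records)
print(f"Euler regions over {n} compounds: {regions}")
for res in resources:
    matched = sum(c for r, c in regions.items() if res.name in r.split("+"))
    print(f"  {res.name}: {matched} matched ({100 * matched / n:.1f}%)")
print(f"exclusive to the patent corpus: {len(exclusive)} ({100 * len(exclusive) / n:.1f}%)")
print(f"clinical phases: {clinical.phase_counts}")
print(f"approval statuses: {clinical.status_counts}")
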