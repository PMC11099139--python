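#!/usr/bin/env python
"""Screen every compound against the 480-pattern PAINS catalog.

Writes the per-alert distinct-compound counts and the hit table.
"""

import json

from _common import ensure_corpus, results_dir

from patentchem.alerts import alert_summary, load_catalog
from patentchem.druglikeness import profile_records
from patentchem.ingest import dedupe, read_map_dump

paths = ensure_corpus()
out = results_dir()

occurrences, _ = read_map_dump(paths.map_file)
profile = profile_records(dedupe(occurrences))
catalog = load_catalog("pains")
summary = alert_summary(zip(profile["inchikey"], profile["smiles"]), catalog)

(out / "pains_summary.json").write_text(
    json.dumps(summary.to_dict(), indent=2) + "\n"
)
summary.hits.to_csv(out / "pains_hits.csv", index=False)

print(f"catalog: {len(catalog)} patterns")
print(f"flagged: {summary.n_flagged}/{summary.n_compounds} compounds "
      f"({100 * summary.flagged_fraction:.2f}%) across {summary.n_alerts_hit} alerts")
for name, count in sorted(summary.per_alert.items(), key=lambda kv: -kv[1])[:5]:
    print(f"  {name}: {count} compounds")
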