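#!/usr/bin/env python
"""Load the map dump: dedupe by InChIKey, promiscuity, jurisdictions.

Writes the load report, the promiscuity histogram, the per-year counts and
the compound-by-(country, kind) table.
"""

import json

from _common import ensure_corpus, results_dir

from patentchem.ingest import (
    dedupe,
    kind_country_table,
    per_year_counts,
    promiscuity_distribution,
    read_map_dump,
)

paths = ensure_corpus()
out = results_dir()

occurrences, report = read_map_dump(paths.map_file)
records = dedupe(occurrences)
hist = promiscuity_distribution(records)

(out / "load_report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
(out / "promiscuity.json").write_text(json.dumps(hist.to_dict(), indent=2) + "\n")
per_year_counts(records).to_csv(out / "per_year_counts.csv", index=False)
kind_country_table(records).to_csv(out / "kind_country.csv", index=False)

n = len(records)
lt5 = hist.bins["1"] + hist.bins["2-4"]
print(f"rows read {report.rows_read}, kept {report.rows_kept}, "
      f"dropped {report.rows_dropped}")
print(f"{n} distinct compounds across {report.occurrences} (compound, patent) pairs")
print(f"promiscuity: {hist.bins} -> {100 * lt5 / n:.1f}% cited in <5 documents")
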