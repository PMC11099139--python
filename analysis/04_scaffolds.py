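#!/usr/bin/env python
"""Bemis-Murcko scaffolds: diversity, yearly novelty, section attribution.

Writes the scaffold table, the per-year new/known counts, the top-10
scaffolds and the per-section attribution.
"""

import json

import pandas as pd

from _common import ensure_corpus, results_dir

from patentchem.druglikeness import profile_records
from patentchem.ingest import dedupe, read_map_dump
from patentchem.scaffolds import (
    mw_distribution,
    novelty_by_year,
    scaffold_section_attribution,
    scaffold_table,
    top_scaffolds,
)

paths = ensure_corpus()
out = results_dir()

occurrences, _ = read_map_dump(paths.map_file)
records = dedupe(occurrences)
profile = profile_records(records)
table = scaffold_table(records, smiles_by_key=dict(zip(profile["inchikey"], profile["smiles"])))

pd.DataFrame(
    [
        {
            "scaffold": r.scaffold_smiles,
            "mw": r.mw,
            "frequency": r.frequency,
            "first_year": r.first_year,
        }
        for r in table.records
    ]
).to_csv(out / "scaffold_table.csv", index=False)
novelty = novelty_by_year(table)
novelty.to_csv(out / "scaffold_novelty.csv", index=False)
scaffold_section_attribution(table).to_csv(out / "scaffold_sections.csv", index=False)
top = top_scaffolds(table, 10)
(out / "top_scaffolds.json").write_text(json.dumps(top, indent=2) + "\n")

print(f"{len(table)} distinct scaffolds; {table.n_acyclic_parents} acyclic parents")
print(f"scaffold MW range: {mw_distribution(table)}")
print("new scaffolds per year:",
      dict(zip(novelty['year'], novelty['new'])))
print("top scaffolds:", [(t["scaffold"], t["frequency"]) for t in top[:5]])
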