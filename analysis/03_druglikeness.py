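#!/usr/bin/env python
"""Desalt, compute descriptors and classify Ro5 / bRo5 / neither.

Writes the per-compound profile, the label shares, the yearly descriptor
means and the top-5 most patent-prevalent compounds per class.
"""

import json

from _common import CORPUS_DIR, ensure_corpus, results_dir

from patentchem.druglikeness import (
    DruglikenessLabel,
    label_shares,
    profile_records,
    top_prevalent,
    yearly_property_means,
)
from patentchem.ingest import dedupe, read_map_dump

paths = ensure_corpus()
out = results_dir()

occurrences, _ = read_map_dump(paths.map_file)
records = dedupe(occurrences)
profile = profile_records(records)
# per-compound table is bulky intermediate data; keep it beside the corpus
profile.to_csv(CORPUS_DIR / "compound_profile.csv", index=False)

shares = label_shares(profile)
(out / "label_shares.json").write_text(json.dumps(shares, indent=2) + "\n")
yearly_property_means(profile).to_csv(out / "yearly_means.csv", index=False)

tops = {}
for label in (DruglikenessLabel.RO5, DruglikenessLabel.BRO5):
    tops[label.value] = [
        {"inchikey": k, "n_patents": c} for k, c in top_prevalent(profile, label, 5)
    ]
(out / "top_prevalent.json").write_text(json.dumps(tops, indent=2) + "\n")

print("drug-likeness shares (% of compounds):")
for label, pct in shares.items():
    print(f"  {label:>8}: {pct:.2f}%")
print("top-5 Ro5 patent counts:", [t["n_patents"] for t in tops["ro5"]])
print("top-5 bRo5 patent counts:", [t["n_patents"] for t in tops["bro5"]])
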