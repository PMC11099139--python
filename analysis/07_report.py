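#!/usr/bin/env python
"""Run the full pipeline and emit the complete summary bundle."""

from _common import ensure_corpus, results_dir

from patentchem.report import PipelineConfig, run_pipeline

paths = ensure_corpus()
out = results_dir()

bundle = run_pipeline(
    PipelineConfig(map_file=paths.map_file, resource_files=paths.resource_files)
)
bundle.to_json(out / "report_bundle.json")
d = bundle.to_dict()

print(f"bundle written to {out / 'report_bundle.json'}")
print(f"  compounds: {d['n_compounds']}")
print(f"  label shares: " + ", ".join(
    f"{k} {v:.1f}%" for k, v in d["label_shares"].items()))
print(f"  PAINS flagged: {d['pains']['flagged_pct']:.2f}%")
print(f"  scaffolds: {d['scaffolds']['n_scaffolds']} "
      f"(+{d['scaffolds']['n_acyclic_parents']} acyclic parents)")
print(f"  exclusive compounds: {d['exclusive']['pct']:.2f}%")
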