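#!/usr/bin/env python
"""Generate the synthetic study corpus.

Emits a SureChEMBL-style map dump (2,000 compounds, years 2015-2022,
55/16/29 Ro5/bRo5/neither split, 4% PAINS injections, 0.9/0.3/0.05
resource overlaps) plus resource tables and the planted ground truth.
"""

import json

from _common import CORPUS_DIR, STUDY_CONFIG, ensure_corpus

paths = ensure_corpus()
truth = json.loads(paths.ground_truth_file.read_text())
agg = truth["aggregates"]

print(f"corpus under {CORPUS_DIR}")
print(f"  compounds: {agg['n_compounds']}  dump rows: {agg['n_rows']}")
print(f"  class counts: {agg['class_counts']}")
print(f"  PAINS-injected: {agg['flagged_count']} "
      f"({100 * agg['flagged_count'] / max(agg['n_compounds'], 1):.1f}%)")
print(f"  planted per resource: {agg['per_resource_counts']}")
print(f"  seed: {STUDY_CONFIG.seed}")
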