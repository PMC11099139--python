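"""Shared plumbing for the numbered analysis drivers.

The corpus lives under scratch/ (regenerated on demand, not committed);
summary tables go to results/analysis/.
"""

from pathlib import Path

from patentchem.synthetic import CorpusPaths, SyntheticConfig, generate_corpus

ROOT = Path(__file__).resolve().parent.parent
CORPUS_DIR = ROOT / "scratch" / "analysis_corpus"
RESULTS_DIR = ROOT / "results" / "analysis"

#: The study conditions shared by every driver.
STUDY_CONFIG = SyntheticConfig(n_compounds=2000, seed=2015)


def ensure_corpus() -> CorpusPaths:
    """Generate the study corpus once; reuse it across drivers."""
    marker = CORPUS_DIR / "ground_truth.json"
    if not marker.exists():
        print(f"generating study corpus ({STUDY_CONFIG.n_compounds} compounds) ...")
        return generate_corpus(STUDY_CONFIG, CORPUS_DIR)
    return CorpusPaths(
        map_file=CORPUS_DIR / "map_dump.tsv",
        resource_files={
            name: CORPUS_DIR / f"resource_{name}.tsv"
            for name in STUDY_CONFIG.resource_overlaps
        },
        ground_truth_file=marker,
    )


def results_dir() -> Path:
    RESULTS_DIR.mkdir(parents=True, exist_ok=True)
    return RESULTS_DIR
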