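import json

import pytest
from hypothesis import HealthCheck, settings

from patentchem.alerts import load_catalog
from patentchem.report import PipelineConfig, run_pipeline
from patentchem.synthetic import SyntheticConfig, generate_corpus

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def pains_catalog():
    return load_catalog("pains")


def _generate(tmp_path_factory, name, config):
    out = tmp_path_factory.mktemp(name)
    paths = generate_corpus(config, out)
    truth = json.loads(paths.ground_truth_file.read_text())
    return config, paths, truth


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A quick 120-compound corpus for per-module recovery checks."""
    return _generate(tmp_path_factory, "corpus_small", SyntheticConfig(n_compounds=120, seed=7))


@pytest.fixture(scope="session")
def study_corpus(tmp_path_factory):
    """The full study conditions: 2,000 compounds, 55/16/29 class split,
    0.9/0.3/0.05 resource overlaps, 4% PAINS injections, fixed seed."""
    return _generate(
        tmp_path_factory, "corpus_study", SyntheticConfig(n_compounds=2000, seed=20150)
    )


@pytest.fixture(scope="session")
def study_bundle(study_corpus):
    config, paths, truth = study_corpus
    bundle = run_pipeline(
        PipelineConfig(map_file=paths.map_file, resource_files=paths.resource_files)
    )
    return bundle.to_dict()
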