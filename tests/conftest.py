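import dataclasses

import pytest
from hypothesis import settings

from asdpheno.embedding import TrigramHashEmbedding
from asdpheno.extraction import load_default_lexicon
from asdpheno.synthetic import CohortConfig, default_scenario, generate_cohorts

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def provider():
    # one instance per session: building the projection matrix is not free
    return TrigramHashEmbedding()


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def small_corpus(scenario):
    """A 60-patients-per-cohort corpus with its ground-truth ledger."""
    cfg, profiles = scenario
    cfg = dataclasses.replace(cfg, n_asd=60, n_psych=60, n_nonpsych=60, seed=11)
    return generate_cohorts(cfg, profiles)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One small end-to-end run shared by the integration tests."""
    from asdpheno.pipeline import PipelineConfig, run_all

    out = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(
        output_dir=str(out), n_asd=150, n_psych=150, n_nonpsych=150,
        top_n_per_cohort=120, tsne_perplexity=20.0, seed=5,
    )
    manifest = run_all(config)
    return config, manifest, out
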