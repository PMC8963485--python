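import numpy as np
import pytest
from hypothesis import settings

from hybridtrace.pipeline import RunConfig, run_pipeline
from hybridtrace.synthetic_data import (default_scenario, simulate_fixture_set,
                                        write_fixture_set)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_set():
    return simulate_fixture_set(FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    write_fixture_set(d, seed=FIXTURE_SEED)
    return d


@pytest.fixture(scope="session")
def pipeline_bundle(fixture_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    config = RunConfig.for_fixture_dir(fixture_dir, out, seed=FIXTURE_SEED)
    bundle = run_pipeline(config)
    bundle["outdir"] = out
    return bundle


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_915)
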