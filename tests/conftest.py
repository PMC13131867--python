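import numpy as np
import pytest

from gpalpha.simulate import GeneratorConfig, generate_cohort, write_fixture


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    return GeneratorConfig(n_patients=4, n_sessions=3)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config, seed=11)


@pytest.fixture(scope="session")
def fixture_dir(tiny_cohort, tiny_config, tmp_path_factory):
    path = tmp_path_factory.mktemp("cohort")
    cohort, truth = tiny_cohort
    write_fixture(cohort, truth, path, tiny_config)
    return path


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
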