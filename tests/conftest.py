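import warnings

import numpy as np
import pytest

from mitecoopt import pipeline
from mitecoopt.synthetic_data import SyntheticConfig, generate_world

# the zero-noise synthetic world makes scipy warn about identical replicates;
# that case is handled explicitly by the accessibility module
warnings.filterwarnings("ignore", message="Precision loss occurred")


@pytest.fixture(scope="session")
def tiny_world(tmp_path_factory):
    """Small two-species world (~0.8 Mb) with full truth tables."""
    out = tmp_path_factory.mktemp("tiny_world")
    cfg = SyntheticConfig.tiny(seed=1)
    truth = generate_world(cfg, out)
    return out, cfg, truth


@pytest.fixture(scope="session")
def tiny_results(tiny_world):
    out, cfg, truth = tiny_world
    res_a = pipeline.run_species(out, "spA")
    res_b = pipeline.run_species(out, "spB")
    return res_a, res_b


@pytest.fixture(scope="session")
def default_world(tmp_path_factory):
    """The benchmark-scale world (~5 Mb) used by the acceptance criteria."""
    out = tmp_path_factory.mktemp("default_world")
    cfg = SyntheticConfig(seed=1)
    truth = generate_world(cfg, out)
    return out, cfg, truth


@pytest.fixture(scope="session")
def default_results(default_world):
    out, cfg, truth = default_world
    res_a = pipeline.run_species(out, "spA")
    res_b = pipeline.run_species(out, "spB")
    return res_a, res_b


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
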