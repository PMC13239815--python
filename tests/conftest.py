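import numpy as np
import pytest

from mpaud.synthetic import SyntheticConfig, make_island_scenario
from mpaud.track_io import AzimuthalEquidistant


@pytest.fixture(scope="session")
def island_scenario(tmp_path_factory):
    """One deterministic island scenario shared across the session."""
    outdir = tmp_path_factory.mktemp("scenario")
    cfg = SyntheticConfig(seed=20260928)
    return cfg, make_island_scenario(cfg, outdir)


@pytest.fixture
def origin_projection():
    return AzimuthalEquidistant(0.0, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
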