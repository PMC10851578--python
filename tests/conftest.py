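import warnings

import numpy as np
import pytest

from understory import StandConfig, generate_stand
from understory.ground import normalize


@pytest.fixture(scope="session")
def open_stand():
    """Open-gap stand (no overstory): saplings fully visible."""
    cfg = StandConfig(
        extent_m=(20.0, 20.0),
        canopy_closure_target=0.0,
        terrain_relief=1.5,
        rng_seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_stand(cfg)


@pytest.fixture(scope="session")
def closed_stand():
    """Two-layer stand with ~40% canopy closure."""
    cfg = StandConfig(
        extent_m=(25.0, 25.0),
        canopy_closure_target=0.4,
        terrain_relief=2.0,
        rng_seed=3,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_stand(cfg)


@pytest.fixture(scope="session")
def closed_stand_normalized(closed_stand):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return normalize(closed_stand.cloud)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
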