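import math

import numpy as np
import pytest

from crcscreen.synthetic import SyntheticConfig, generate_slide, iter_slides


@pytest.fixture(scope="session")
def default_slide():
    """One full-size generator slide (3x3 tile grid, mpp 4, high risk)."""
    cfg = SyntheticConfig(n_slides=2, high_risk_prevalence=1.0, seed=11)
    return generate_slide(cfg, 0)


@pytest.fixture(scope="session")
def small_config():
    """A miniature generator setup for tests whose property is size-free."""
    return SyntheticConfig(
        n_slides=200,
        image_size=(320, 240),
        mpp=4.0,
        area_lognormal=(math.log(0.004), 0.4),
        seed=5,
    )


@pytest.fixture(scope="session")
def default_cohort_20():
    """Twenty default-geometry slides for oracle cross-checks."""
    cfg = SyntheticConfig(n_slides=20, high_risk_prevalence=0.6, seed=23)
    return list(iter_slides(cfg))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
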