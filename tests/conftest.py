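import numpy as np
import pytest

from reachkin.kinematics import SkeletonTemplate
from reachkin.synthetic import (
    PopulationConfig,
    SyntheticConfig,
    generate_session,
)


@pytest.fixture(scope="session")
def template():
    return SkeletonTemplate.default()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """A modest full session shared by read-only tests."""
    cfg = SyntheticConfig(
        n_trials=30, seed=7, glitch_fraction=0.0,
        populations={
            "A": PopulationConfig(n_rois=50),
            "B": PopulationConfig(n_rois=50, target_latency_ms=140.0),
        },
    )
    return generate_session(cfg)
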