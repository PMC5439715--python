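import numpy as np
import pytest
from hypothesis import settings

from regrowth.survival import LQParameters, lq_from_survival_points

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# the two printed clonogenic survival points the LQ curve is anchored to
POINT_8GY = (8.0, 0.0255)
POINT_16GY = (16.0, 0.00009)


@pytest.fixture(scope="session")
def lq_anchored() -> LQParameters:
    """LQ parameters interpolated exactly through the two anchor points."""
    return lq_from_survival_points(POINT_8GY, POINT_16GY)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
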