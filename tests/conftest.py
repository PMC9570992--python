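import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from dashphen.detections import BoundingBox

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

A_DATE = dt.date(2020, 3, 3)


@st.composite
def boxes(draw, max_coord=100, dated=True):
    """Random valid bounding boxes in a max_coord x max_coord frame."""
    x0 = draw(st.integers(0, max_coord - 2))
    y0 = draw(st.integers(0, max_coord - 2))
    x1 = draw(st.integers(x0 + 1, max_coord))
    y1 = draw(st.integers(y0 + 1, max_coord))
    conf = draw(st.floats(0.0, 1.0, allow_nan=False))
    return BoundingBox(
        x_min=x0, y_min=y0, x_max=x1, y_max=y1,
        confidence=round(conf, 6), date=A_DATE if dated else None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
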