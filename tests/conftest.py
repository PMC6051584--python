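import datetime as dt

import pytest

from pamsurvey.synthetic_data import (
    ActivityShape,
    SiteConfig,
    default_activity_shape,
)


@pytest.fixture(scope="session")
def flat_shape():
    """Curves all at 1: a homogeneous Poisson process."""
    start = dt.date(2016, 8, 1)
    return ActivityShape(
        diel_curve={b: 1.0 for b in range(-12, 12)},
        seasonal_curve={w: 1.0 for w in range(0, 30)},
        week_origin=start,
    )


@pytest.fixture(scope="session")
def default_shape():
    return default_activity_shape()


@pytest.fixture
def one_site():
    return SiteConfig("A", density=1.5, base_rate=2.0, latitude=-38.0, longitude=145.0)
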