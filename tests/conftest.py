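import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sunflight import FlightSummary, HeadingTrace

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_trace(
    heading,
    fly_id="fly1",
    group="ctrl",
    flight_type="sun",
    flight_index=1,
    duration_s=300.0,
    n=None,
    n_stops=0,
    stop_intervals=(),
):
    """Trace with constant or array heading over a given duration."""
    heading = np.atleast_1d(np.asarray(heading, dtype=float))
    if n is None:
        n = heading.size if heading.size > 1 else 50
    if heading.size == 1:
        heading = np.full(n, heading[0])
    t = np.linspace(0.0, duration_s, heading.size)
    return HeadingTrace(
        fly_id=fly_id,
        group=group,
        flight_type=flight_type,
        flight_index=flight_index,
        t=t,
        heading=heading,
        n_stops=n_stops,
        stop_intervals=list(stop_intervals),
    )


def make_summary(
    fly_id,
    mean_heading=0.0,
    vector_strength=0.5,
    group="ctrl",
    flight_type="sun",
    flight_index=1,
):
    mh = float(mean_heading)
    return FlightSummary(
        fly_id=fly_id,
        group=group,
        flight_type=flight_type,
        flight_index=flight_index,
        mean_heading=mh,
        vector_strength=float(vector_strength),
        abs_mean_heading=abs(mh) if math.isfinite(mh) else math.nan,
        n_samples=100,
        duration_s=300.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
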