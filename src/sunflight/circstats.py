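"""Per-flight circular statistics for tethered-flight heading traces.

A fly flying in closed loop to a sun-like stimulus holds a "heading": the
angular position of the stimulus relative to the fly, 0 deg meaning the
stimulus is directly in front, signed and wrapped to (-180, 180].  The two
per-flight quantities of interest are

* the circular mean heading -- the angle of the resultant vector obtained
  by summing one unit vector per heading sample, and
* the vector strength -- the length of that resultant divided by the number
  of samples, in [0, 1]; 1 means a perfectly constant heading, 0 means no
  directional consistency.

All angles are handled in degrees end-to-end.  Samples are equally weighted
regardless of timestamp jitter (the acquisition rate is nominal).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Resultant lengths below this are treated as degenerate: the direction of a
#: (numerically) zero-length resultant carries no information, so the mean
#: heading is flagged undefined (NaN) instead of returning an arbitrary angle.
DEGENERATE_RESULTANT = 1e-12

VALID_FLIGHT_TYPES = ("sun", "stripe")


def wrap_deg(angle):
    """Wrap an angle (or array of angles) in degrees to (-180, 180]."""
    a = np.mod(np.asarray(angle, dtype=float), 360.0)
    a = np.where(a > 180.0, a - 360.0, a)
    if np.ndim(angle) == 0:
        return float(a)
    return a


def resultant_vector(headings):
    """Circular mean and vector strength of a set of headings in degrees.

    Each heading is treated as a unit vector; the vectors are summed and the
    resultant length is normalised by the number of headings.

    Parameters
    ----------
    headings : array-like of float
        Heading angles in degrees.  Any finite real values; wrapping is
        implicit in the trigonometry.

    Returns
    -------
    (mean_heading, vector_strength)
        ``mean_heading`` in (-180, 180], or NaN when the resultant is
        degenerate (length below ``DEGENERATE_RESULTANT``);
        ``vector_strength`` in [0, 1].

    Raises
    ------
    ValueError
        On empty input or non-finite angles.
    """
    h = np.asarray(headings, dtype=float)
    if h.size == 0:
        raise ValueError("no headings")
    if not np.all(np.isfinite(h)):
        raise ValueError("non-finite heading value")
    rad = np.deg2rad(h.ravel())
    c = float(np.cos(rad).sum())
    s = float(np.sin(rad).sum())
    r = min(math.hypot(c, s) / h.size, 1.0)
    if r < DEGENERATE_RESULTANT:
        return math.nan, r
    return wrap_deg(math.degrees(math.atan2(s, c))), r


def fold_abs(heading):
    """Fold a heading to its absolute value in [0, 180].

    0 = stimulus directly in front, 180 = directly behind.  The angle is
    wrapped to (-180, 180] first, so any finite real input is accepted.
    Idempotent and even: ``fold_abs(-x) == fold_abs(x)``.
    """
    h = np.asarray(heading, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("non-finite heading value")
    out = np.abs(wrap_deg(h))
    if np.ndim(heading) == 0:
        return float(out)
    return out


@dataclass
class HeadingTrace:
    """One flight's heading time series plus cohort metadata.

    ``t`` is in seconds and strictly increasing; ``heading`` is in degrees
    and is wrapped to (-180, 180] on construction.  ``n_stops`` counts flight
    stoppages during the trial (used by QC); ``stop_intervals`` optionally
    records their [start_s, end_s] extents.
    """

    fly_id: str
    group: str
    flight_type: str
    flight_index: int
    t: np.ndarray
    heading: np.ndarray
    n_stops: int = 0
    stop_intervals: list = field(default_factory=list)

    def __post_init__(self):
        if self.flight_type not in VALID_FLIGHT_TYPES:
            raise ValueError(
                f"flight_type must be one of {VALID_FLIGHT_TYPES}, "
                f"got {self.flight_type!r}"
            )
        if int(self.flight_index) != self.flight_index or self.flight_index < 1:
            raise ValueError("flight_index must be an integer >= 1")
        self.flight_index = int(self.flight_index)
        self.t = np.asarray(self.t, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        if self.t.ndim != 1 or self.heading.ndim != 1:
            raise ValueError("t and heading must be 1-D")
        if self.t.size != self.heading.size:
            raise ValueError("t and heading must have equal length")
        if self.t.size == 0:
            raise ValueError("empty trace")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite time value")
        if not np.all(np.isfinite(self.heading)):
            raise ValueError("non-finite heading value")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        self.heading = wrap_deg(self.heading)
        if self.n_stops < 0:
            raise ValueError("n_stops must be non-negative")
        self.stop_intervals = [
            (float(a), float(b)) for a, b in (self.stop_intervals or [])
        ]
        if self.n_stops < len(self.stop_intervals):
            raise ValueError("n_stops smaller than number of stop_intervals")
        for a, b in self.stop_intervals:
            if b < a:
                raise ValueError(f"stop interval [{a}, {b}] has end < start")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class FlightSummary:
    """Circular summary of a single flight.

    ``mean_heading`` (degrees, (-180, 180]) and ``abs_mean_heading``
    (degrees, [0, 180]) are NaN when the resultant is degenerate;
    ``vector_strength`` is always defined, in [0, 1].
    """

    fly_id: str
    group: str
    flight_type: str
    flight_index: int
    mean_heading: float
    vector_strength: float
    abs_mean_heading: float
    n_samples: int
    duration_s: float
    n_stops: int = 0
    qc_pass: bool = True


def summarize_flight(trace: HeadingTrace, exclude_stops: bool = False) -> FlightSummary:
    """Summarise a flight: circular mean heading, vector strength, |heading|.

    Every heading sample carries equal weight.  By default samples that fall
    inside ``stop_intervals`` are retained (QC operates on whole flights via
    stop counts, not on individual samples); pass ``exclude_stops=True`` to
    mask them out.
    """
    h = trace.heading
    if exclude_stops and trace.stop_intervals:
        keep = np.ones(trace.t.size, dtype=bool)
        for a, b in trace.stop_intervals:
            keep &= ~((trace.t >= a) & (trace.t <= b))
        if not keep.any():
            raise ValueError("no headings outside stop intervals")
        h = h[keep]
    mean, strength = resultant_vector(h)
    return FlightSummary(
        fly_id=trace.fly_id,
        group=trace.group,
        flight_type=trace.flight_type,
        flight_index=trace.flight_index,
        mean_heading=mean,
        vector_strength=strength,
        abs_mean_heading=fold_abs(mean) if math.isfinite(mean) else math.nan,
        n_samples=int(h.size if exclude_stops else trace.n_samples),
        duration_s=trace.duration_s,
        n_stops=trace.n_stops,
    )
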