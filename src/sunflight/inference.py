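"""Fly-level permutation tests and bootstrap CIs for heading statistics.

Flights from the same fly are not independent (each fly flies twice toward
its own goal heading), so resampling at the flight level would
pseudoreplicate.  Both procedures here therefore treat the FLY as the
exchangeable/resampling unit while the statistic itself averages over
FLIGHTS:

* :func:`permutation_test` -- two-sided randomisation test on the difference
  of group means of a per-flight value (folded absolute heading or vector
  strength).  Whole flies are reassigned between groups, preserving the
  original fly counts; flight-count imbalance across permutations is
  accepted.  p uses the add-one estimator
  ``(1 + #{|null| >= |observed|}) / (n_perm + 1)``.
* :func:`bootstrap_circular_ci` -- percentile CI of the circular mean of
  per-flight mean headings, resampling flies with replacement at matched fly
  count, each sampled fly contributing all of its qualifying flights.  The
  percentile interval is taken on signed angular deviations from the
  observed circular mean and re-centred, so intervals spanning the +-180
  seam never invert.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circstats import DEGENERATE_RESULTANT, wrap_deg

STATISTICS = ("abs_heading_mean_diff", "vector_strength_mean_diff")

DEFAULT_N_PERM = 10_000
DEFAULT_N_BOOT = 10_000


@dataclass
class PermutationResult:
    statistic_name: str
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int


@dataclass
class BootstrapCI:
    """Wraparound-aware percentile CI of a circular mean (degrees)."""

    mean_heading: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    coverage_level: float
    boot_means: np.ndarray = field(repr=False, default=None)
    n_degenerate: int = 0

    def contains(self, angle: float) -> bool:
        """Circular containment: is ``angle`` on the arc low -> high?"""
        span = np.mod(self.ci_high - self.ci_low, 360.0)
        offs = np.mod(angle - self.ci_low, 360.0)
        return bool(offs <= span + 1e-9)


def _flight_value(summary, statistic: str) -> float:
    if statistic == "abs_heading_mean_diff":
        v = summary.abs_mean_heading
        if not math.isfinite(v):
            raise ValueError(
                f"flight ({summary.fly_id}, {summary.flight_type}, "
                f"{summary.flight_index}) has undefined mean heading; "
                "filter flights by vector strength first"
            )
        return v
    if statistic == "vector_strength_mean_diff":
        return summary.vector_strength
    raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")


def _fly_aggregates(summaries, statistic):
    """Per-fly (value sum, flight count), preserving first-seen fly order."""
    sums: dict = {}
    counts: dict = {}
    for s in summaries:
        v = _flight_value(s, statistic)
        sums[s.fly_id] = sums.get(s.fly_id, 0.0) + v
        counts[s.fly_id] = counts.get(s.fly_id, 0) + 1
    ids = list(sums)
    return (
        ids,
        np.array([sums[i] for i in ids]),
        np.array([counts[i] for i in ids], dtype=float),
    )


def permutation_test(
    group_a,
    group_b,
    statistic: str = "abs_heading_mean_diff",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> PermutationResult:
    """Fly-level randomisation test of a flight-mean group difference.

    ``group_a`` and ``group_b`` are lists of FlightSummary; the groups must
    involve disjoint sets of flies.  The observed statistic is the
    flight-level mean of the chosen per-flight value in A minus that in B.
    The null distribution reassigns whole flies (all flights attached) to
    groups of the original fly counts, uniformly at random.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not group_a or not group_b:
        raise ValueError("empty group")
    ids_a, sums_a, counts_a = _fly_aggregates(group_a, statistic)
    ids_b, sums_b, counts_b = _fly_aggregates(group_b, statistic)
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise ValueError(f"flies appear in both groups: {sorted(overlap)}")

    observed = float(sums_a.sum() / counts_a.sum() - sums_b.sum() / counts_b.sum())

    sums = np.concatenate([sums_a, sums_b])
    counts = np.concatenate([counts_a, counts_b])
    n_a, n = len(ids_a), len(ids_a) + len(ids_b)
    tot_sum, tot_cnt = sums.sum(), counts.sum()

    rng = np.random.default_rng(seed)
    # one uniform draw per (permutation, fly); the n_a smallest keys per row
    # form group A -- a uniform random fly assignment at fixed group sizes
    idx = np.argsort(rng.random((int(n_perm), n)), axis=1)[:, :n_a]
    sum_a = sums[idx].sum(axis=1)
    cnt_a = counts[idx].sum(axis=1)
    null = sum_a / cnt_a - (tot_sum - sum_a) / (tot_cnt - cnt_a)

    # ties between |null| and |observed| count as at-least-as-extreme; the
    # small slack absorbs summation-order float noise on exact ties
    tol = 1e-9 * (1.0 + abs(observed))
    exceed = int(np.count_nonzero(np.abs(null) >= abs(observed) - tol))
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(
        statistic_name=statistic,
        observed_stat=observed,
        null_stats=null,
        p_value=p,
        n_perm=int(n_perm),
        seed=seed,
    )


def bootstrap_circular_ci(
    flights,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    level: float = 0.95,
) -> BootstrapCI:
    """Fly-level bootstrap CI of the circular mean of flight mean headings.

    ``flights`` is a list of FlightSummary, pre-filtered to directionally
    consistent flights (vector strength above threshold), from a single
    group.  Each of the ``n_boot`` resamples draws flies with replacement at
    the observed fly count, each sampled fly contributing all its qualifying
    flights; the resample statistic is the circular mean of the per-flight
    mean headings.  A resample whose resultant is degenerate is recorded as
    undefined and excluded from the percentiles (counted in
    ``n_degenerate``).
    """
    if not flights:
        raise ValueError("no qualifying flights")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    cos_sums: dict = {}
    sin_sums: dict = {}
    for s in flights:
        if not math.isfinite(s.mean_heading):
            raise ValueError(
                f"flight ({s.fly_id}, {s.flight_type}, {s.flight_index}) has "
                "undefined mean heading; filter flights by vector strength first"
            )
        rad = math.radians(s.mean_heading)
        cos_sums[s.fly_id] = cos_sums.get(s.fly_id, 0.0) + math.cos(rad)
        sin_sums[s.fly_id] = sin_sums.get(s.fly_id, 0.0) + math.sin(rad)
    ids = list(cos_sums)
    C = np.array([cos_sums[i] for i in ids])
    S = np.array([sin_sums[i] for i in ids])
    n_fly = len(ids)
    n_flights = len(flights)

    obs_c, obs_s = C.sum(), S.sum()
    if math.hypot(obs_c, obs_s) / n_flights < DEGENERATE_RESULTANT:
        raise ValueError("degenerate circular mean of observed headings")
    observed = wrap_deg(math.degrees(math.atan2(obs_s, obs_c)))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_fly, size=(int(n_boot), n_fly))
    Cb = C[idx].sum(axis=1)
    Sb = S[idx].sum(axis=1)
    degenerate = np.hypot(Cb, Sb) < DEGENERATE_RESULTANT * n_flights
    boot = wrap_deg(np.degrees(np.arctan2(Sb, Cb)))
    boot[degenerate] = np.nan

    dev = wrap_deg(boot - observed)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.nanpercentile(dev, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(
        mean_heading=observed,
        ci_low=wrap_deg(observed + lo),
        ci_high=wrap_deg(observed + hi),
        n_boot=int(n_boot),
        seed=seed,
        coverage_level=level,
        boot_means=boot,
        n_degenerate=int(degenerate.sum()),
    )
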