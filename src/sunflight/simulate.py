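"""Closed-loop tethered-flight simulator and synthetic cohort generator.

In the arena a tethered fly steers a visual stimulus (a 2.4-degree
sun-like dot, or a 15 x 60-degree dark stripe) with its wing-stroke
amplitude difference (delta-WBA): the stimulus angular velocity equals
``gain x delta-WBA`` with gain 4.75 (deg/s per deg of wing-stroke
difference).  Wing kinematics are tracked at 60 Hz while the stimulus
position -- the fly's virtual heading -- is recorded at 200 Hz.  Each fly
flies two 5-minute sun trials separated by a rest period, optionally
followed by a stripe trial.

The synthetic fly is a proportional controller: it holds a fixed goal
heading per flight and produces a wing-stroke difference proportional to
the (wrapped) heading error, plus white Gaussian noise.  The policy is
updated at the wing-tracking rate and held constant (zero-order hold)
while the heading integrates at the stimulus rate, mirroring the two
acquisition rates.  This is the simplest controller whose stationary
heading distribution is von-Mises-like, so its concentration maps directly
onto per-flight vector strength.

Seed discipline: a master seed spawns per-flight ``numpy`` SeedSequences
via :func:`flight_seed` (keyed by group index, fly index and flight code),
so any single flight can be regenerated in isolation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circstats import HeadingTrace, wrap_deg
from .io import Cohort, FlyRecord

#: Arena gain: stimulus angular velocity per degree of wing-stroke
#: difference (deg/s per deg).
ARENA_GAIN = 4.75

#: Flight codes used in per-flight seed derivation.
SUN_FLIGHT_CODES = (1, 2)
STRIPE_FLIGHT_CODE = 101


@dataclass
class SimConfig:
    """Arena and trial-structure parameters.

    Defaults are the experimental conditions: gain 4.75 deg/s per deg,
    5-minute trials, 200 Hz heading samples, 60 Hz policy (wing-tracking)
    updates, a ~2.4-degree sun and a 15 x 60-degree stripe.  ``seed`` is the
    default master seed for cohort generation (overridable per call).
    """

    gain: float = ARENA_GAIN
    duration_s: float = 300.0
    heading_rate_hz: float = 200.0
    policy_rate_hz: float = 60.0
    sun_size_deg: float = 2.4
    stripe_size_deg: tuple = (15.0, 60.0)
    stop_rate_per_flight: float = 0.3
    stop_duration_s: float = 2.0
    n_sun_flights: int = 2
    include_stripe: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.heading_rate_hz <= 0 or self.policy_rate_hz <= 0:
            raise ValueError("rates must be positive")
        if self.stop_rate_per_flight < 0:
            raise ValueError("stop_rate_per_flight must be non-negative")


@dataclass
class FlyPhenotype:
    """One fly's behavioural parameters for a flight.

    ``goal_deg`` -- preferred heading; ``k_p`` -- proportional steering gain
    (1/s): the effective exponential rate at which heading error decays;
    ``sigma_w`` -- wing-stroke difference noise SD (deg) per policy update.
    """

    goal_deg: float
    k_p: float
    sigma_w: float

    def __post_init__(self):
        if self.k_p < 0:
            raise ValueError("k_p must be non-negative")
        if self.sigma_w < 0:
            raise ValueError("sigma_w must be non-negative")


@dataclass
class GroupSpec:
    """Group-level distribution from which fly phenotypes are drawn.

    Goal headings come from a two-component mixture: with probability
    ``frontal_prob`` a von Mises centred frontally (mu_frontal, kappa
    ``kappa_frontal``), otherwise a broad/rear component (mu_rear, kappa
    ``kappa_rear``; kappa 0 = uniform).  ``sigma_w`` is an effective,
    lumped noise magnitude, not a literal wing-kinematic value.
    """

    label: str
    n_flies: int
    frontal_prob: float = 0.0
    mu_frontal: float = 0.0
    kappa_frontal: float = 8.0
    mu_rear: float = 180.0
    kappa_rear: float = 0.5
    k_p: float = 0.3
    sigma_w: float = 80.0
    stop_rate: float | None = None

    def __post_init__(self):
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if not 0.0 <= self.frontal_prob <= 1.0:
            raise ValueError("frontal_prob must be in [0, 1]")
        if self.kappa_frontal < 0 or self.kappa_rear < 0:
            raise ValueError("kappa must be non-negative")


def frontal_group_spec(label="frontal", n_flies=20, **kw) -> GroupSpec:
    """All goals frontal: von Mises(0 deg, kappa 8)."""
    return GroupSpec(label=label, n_flies=n_flies, frontal_prob=1.0, **kw)


def broad_group_spec(label="broad", n_flies=20, **kw) -> GroupSpec:
    """Broad goals with a slight rear bias: von Mises(180 deg, kappa 0.5)."""
    return GroupSpec(label=label, n_flies=n_flies, frontal_prob=0.0, **kw)


def closed_loop_step(heading, wing_diff, dt, gain=ARENA_GAIN):
    """Advance the stimulus one step: heading' = wrap(heading + gain*wing_diff*dt).

    Positive wing-stroke difference drives positive (rightward) stimulus
    angular velocity.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (math.isfinite(heading) and math.isfinite(wing_diff) and math.isfinite(dt)):
        raise ValueError("non-finite input")
    return wrap_deg(heading + gain * wing_diff * dt)


def steering_policy(heading, goal, k_p, sigma_w, rng, gain=ARENA_GAIN):
    """Proportional wing-stroke difference steering heading toward goal.

    wing_diff = -(k_p / gain) * wrap(heading - goal) + N(0, sigma_w), so the
    closed loop relaxes heading error at rate ``k_p`` (1/s).
    """
    if sigma_w < 0:
        raise ValueError("sigma_w must be non-negative")
    err = wrap_deg(heading - goal)
    w = -(k_p / gain) * err
    if sigma_w > 0:
        w += rng.normal(0.0, sigma_w)
    return w


def _draw_stops(rng, rate, duration_s, stop_duration_s):
    """Poisson stop count; intervals placed uniformly within the flight."""
    n_stops = int(rng.poisson(rate)) if rate > 0 else 0
    intervals = []
    if n_stops > 0:
        length = min(stop_duration_s, duration_s)
        starts = np.sort(rng.uniform(0.0, max(duration_s - length, 0.0), n_stops))
        intervals = [(float(s), float(s + length)) for s in starts]
    return n_stops, intervals


def simulate_flight(
    phenotype: FlyPhenotype,
    config: SimConfig,
    seed,
    fly_id: str = "sim",
    group: str = "sim",
    flight_type: str = "sun",
    flight_index: int = 1,
    start_heading: float | None = None,
    stop_rate: float | None = None,
) -> HeadingTrace:
    """Simulate one closed-loop flight; deterministic per seed.

    The policy (wing-stroke difference) updates at ``policy_rate_hz`` and is
    held between updates while the heading advances linearly, then the trace
    is sampled at ``heading_rate_hz`` (``duration_s * heading_rate_hz``
    samples starting at t=0).  RNG draw order: start heading (uniform, if
    not given), policy noise sequence, stop count, stop placements.
    """
    if not isinstance(config, SimConfig):
        raise ValueError("config must be a SimConfig")
    rng = np.random.default_rng(seed)
    if start_heading is None:
        start_heading = rng.uniform(-180.0, 180.0)

    gain = config.gain
    dt_p = 1.0 / config.policy_rate_hz
    n_policy = int(round(config.duration_s * config.policy_rate_hz))
    noise = (
        rng.normal(0.0, phenotype.sigma_w, n_policy)
        if phenotype.sigma_w > 0
        else np.zeros(n_policy)
    )

    # error-coordinate recursion at the policy grid; scalar loop for speed
    goal = float(phenotype.goal_deg)
    kpg = phenotype.k_p / gain
    b = gain * dt_p
    e = wrap_deg(start_heading - goal)
    noise_list = noise.tolist()
    err = np.empty(n_policy)
    for j in range(n_policy):
        err[j] = e
        w = -kpg * e + noise_list[j]
        e += b * w
        if e > 180.0:
            e -= 360.0
        elif e <= -180.0:
            e += 360.0

    wings = -kpg * err + noise  # held wing-stroke difference per interval
    h_policy = goal + err  # wrapped when the trace is built

    n_samples = int(round(config.duration_s * config.heading_rate_hz))
    t = np.arange(n_samples) / config.heading_rate_hz
    j = np.minimum((t * config.policy_rate_hz).astype(int), n_policy - 1)
    heading = h_policy[j] + gain * wings[j] * (t - j * dt_p)

    rate = config.stop_rate_per_flight if stop_rate is None else stop_rate
    n_stops, intervals = _draw_stops(rng, rate, config.duration_s, config.stop_duration_s)
    return HeadingTrace(
        fly_id=fly_id,
        group=group,
        flight_type=flight_type,
        flight_index=flight_index,
        t=t,
        heading=heading,
        n_stops=n_stops,
        stop_intervals=intervals,
    )


def flight_seed(master_seed: int, group_index: int, fly_index: int, flight_code: int):
    """SeedSequence for one flight, regenerable in isolation."""
    return np.random.SeedSequence([int(master_seed), group_index, fly_index, flight_code])


def _fly_rng(master_seed, group_index, fly_index):
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), group_index, fly_index])
    )


def _draw_goal(rng, spec: GroupSpec) -> float:
    frontal = rng.random() < spec.frontal_prob
    mu = spec.mu_frontal if frontal else spec.mu_rear
    kappa = spec.kappa_frontal if frontal else spec.kappa_rear
    if kappa < 1e-9:
        return float(rng.uniform(-180.0, 180.0))
    return wrap_deg(math.degrees(rng.vonmises(math.radians(mu), kappa)))


def generate_cohort(specs, config: SimConfig | None = None, seed=None) -> Cohort:
    """Generate a synthetic cohort: per fly, a goal/phenotype draw from its
    GroupSpec and two sun flights (fresh per-flight seeds, same goal),
    optionally followed by a stripe flight with a frontally biased stripe
    goal (von Mises(0 deg, kappa 4), fixation-like).
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    labels = [s.label for s in specs]
    if len(labels) != len(set(labels)):
        raise ValueError(f"duplicate group labels: {labels}")
    config = config or SimConfig()
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a master seed is required (config.seed or seed=)")

    groups: dict = {}
    for gi, spec in enumerate(specs):
        flies = []
        for fi in range(spec.n_flies):
            fly_id = f"{spec.label}_{fi + 1:03d}"
            fly_rng = _fly_rng(seed, gi, fi)
            goal = _draw_goal(fly_rng, spec)
            stripe_goal = wrap_deg(math.degrees(fly_rng.vonmises(0.0, 4.0)))
            phen = FlyPhenotype(goal_deg=goal, k_p=spec.k_p, sigma_w=spec.sigma_w)
            flights = []
            for code in SUN_FLIGHT_CODES[: config.n_sun_flights]:
                flights.append(
                    simulate_flight(
                        phen,
                        config,
                        flight_seed(seed, gi, fi, code),
                        fly_id=fly_id,
                        group=spec.label,
                        flight_type="sun",
                        flight_index=code,
                        stop_rate=spec.stop_rate,
                    )
                )
            if config.include_stripe:
                stripe_phen = FlyPhenotype(
                    goal_deg=stripe_goal, k_p=spec.k_p, sigma_w=spec.sigma_w
                )
                flights.append(
                    simulate_flight(
                        stripe_phen,
                        config,
                        flight_seed(seed, gi, fi, STRIPE_FLIGHT_CODE),
                        fly_id=fly_id,
                        group=spec.label,
                        flight_type="stripe",
                        flight_index=1,
                        stop_rate=spec.stop_rate,
                    )
                )
            flies.append(FlyRecord(fly_id=fly_id, group=spec.label, flights=flights))
        groups[spec.label] = flies
    return Cohort(groups=groups, provenance=f"simulated (master seed {seed})")
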