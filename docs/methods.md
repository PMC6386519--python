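# Methods

## Angles and per-flight statistics

All angles are degrees end-to-end, wrapped to (−180°, 180°]; the wrap
convention places the seam at ±180° with 180° included, and 0° means the
stimulus is directly in front of the fly.  A flight's circular mean
heading is the angle of the resultant of one unit vector per heading
sample; the vector strength ρ is the resultant length divided by the
number of samples.  Samples are equally weighted regardless of timestamp
jitter — the acquisition rate is nominal (200 Hz) and no resampling to a
uniform grid is performed.  When |R|/n falls below 1e-12 the direction is
numerically meaningless, so the mean heading is flagged undefined (NaN)
rather than returning an arbitrary angle; downstream heading analyses
never see such flights because of the ρ > 0.2 filter.

Samples that fall inside recorded stop intervals are **included** in
per-flight statistics by default: quality control acts on whole flights
via stop counts, and nothing in the analysis definition masks individual
samples.  Masking is available (`summarize_flight(..., exclude_stops=True)`)
but off by default.

## QC and filtering

Rules are applied in order: (1) discard flights in which the fly stopped
flying more than once; (2) discard **all** flights of any fly that did
not complete both 5-minute sun flights.  "Completed" is duration ≥ 0.95 ×
the nominal 300 s trial (the completeness fraction and trial duration are
parameters; recordings are often a sample short of the nominal length,
hence a tolerance rather than equality).  The completion rule is
evaluated after the stop rule, so losing one sun flight to the stop rule
also removes the fly.  Heading-distribution analyses and confidence
intervals additionally keep only flights with vector strength strictly
above 0.2 — "above" read as a strict inequality, so ρ = 0.2 exactly is
excluded.

## Fly-level inference

Each fly contributes two flights driven by the same goal heading, so
flights are pseudoreplicates.  Exchangeability is therefore imposed at
the fly level while the statistics remain flight-level means (matching
how per-flight distributions are summarised):

- **Permutation test.**  Observed statistic: mean over group-A flights
  minus mean over group-B flights of the per-flight value (folded
  absolute heading, or vector strength).  Null: whole flies (with all
  their flights) reassigned uniformly at random to groups of the original
  *fly* counts; flight-count imbalance across permutations is accepted.
  Two-sided p via the add-one estimator (1 + #{|null| ≥ |obs|}) /
  (n_perm + 1), which is never zero; ties count as at-least-as-extreme,
  with a 1e-9 relative slack absorbing summation-order float noise on
  exact ties.  Default 10,000 permutations.
- **Bootstrap CI.**  Statistic: circular mean of per-flight mean
  headings.  Each resample draws flies with replacement at the observed
  fly count ("matched size" interpreted as matched fly count), each
  sampled fly contributing all of its ρ-qualifying flights.  The 95%
  interval is the percentile interval of signed angular deviations from
  the observed circular mean, re-centred — equivalent to rotating the
  data to 0°, taking a naive percentile interval, and rotating back — so
  intervals spanning the ±180° seam never invert.  A resample with a
  degenerate resultant is recorded as undefined and excluded from the
  percentiles (counted in `n_degenerate`).  Default 10,000 resamples.

The group mean of folded headings is a **linear** mean of |θ̄| values (the
cumulative-distribution summaries it mirrors are linear in the folded
variable); the CI is on the **circular** mean.  The vector-strength
comparison uses all QC-passing flights — the ρ > 0.2 gate exists to make
heading *directions* meaningful and is not applied to the consistency
statistic itself.

All resampling takes explicit integer seeds.  The pipeline derives
per-test and per-group sub-seeds from its master seed with a CRC-keyed
`SeedSequence`, so reports regenerate byte-identically.

## The closed-loop simulator

The arena couples stimulus angular velocity to the wing-stroke amplitude
difference at gain 4.75 °/s per degree.  The synthetic fly is a
proportional controller with white noise:

    wing_diff = −(k_p / gain) · wrap(heading − goal) + N(0, σ_w)

updated at the 60 Hz wing-tracking rate and held (zero-order hold) while
the heading integrates at the 200 Hz stimulus rate.  The heading error
follows a wrapped AR(1)/Ornstein–Uhlenbeck-like process, so stationary
heading distributions are von-Mises-like and per-flight vector strength
maps monotonically onto the noise level.  Start headings are uniform.

Parameters and defaults (chosen once as the study conditions):

| parameter | default | meaning |
|---|---|---|
| `gain` | 4.75 °/s per ° | arena closed-loop gain |
| `duration_s` | 300 s | trial length (two sun flights per fly) |
| `heading_rate_hz` / `policy_rate_hz` | 200 / 60 Hz | stimulus vs wing-tracking rates |
| `k_p` | 0.3 s⁻¹ | error-decay rate (≈3 s heading correlation time) |
| `σ_w` | 80° | ΔWBA noise SD per policy update |
| frontal goals | von Mises(0°, κ=8) | frontally concentrated goal headings |
| broad goals | von Mises(180°, κ=0.5) | near-uniform with a slight rear bias |
| stops | Poisson(0.3)/flight, 2 s each | placed uniformly; samples retained |

`σ_w` is an *effective*, lumped noise magnitude: real heading meander is
dominated by slowly drifting steering, not white wing noise, so matching
realistic per-flight vector strengths with a white-noise controller
requires a σ_w far above literal wing-kinematic variability.  The default
yields per-flight ρ mostly in 0.4–0.8 with occasional flights below the
0.2 threshold, i.e. a regime where every filtering stage is exercised.
What the simulator does **not** emulate: within-flight goal switching,
slow drift and saccade structure, stopping that alters the trace itself
(stops only annotate metadata), learning across flights, and any visual-
system or aerodynamic realism.  Passing tests therefore validate the
statistical machinery under the assumed dependence structure — per-fly
goals, two flights per fly — not the behavioural realism of real flies.

Seed discipline: the master seed plus (group index, fly index, flight
code) key a `SeedSequence` per flight (sun flights 1 and 2; stripe 101),
so any flight regenerates in isolation.  Stripe flights reuse the same
controller with a frontally biased stripe goal (von Mises(0°, κ=4)),
reflecting stripe fixation; stripe analyses reuse the sun machinery
verbatim and never mix with sun tests.

## Brp density

Background per pixel is the unweighted mean over all background-ROI
pixels pooled together.  It is subtracted from each pixel of the
rectangular Gall ROI; negative remainders are clipped to zero (the
subtraction is defined per value without addressing negatives — clipping
is this package's choice and introduces a small positive bias only where
near-background pixels fall inside the Gall ROI).  The clipped values are
summed and divided by the Gall area: the shoelace area of the manual
polygon times the physical area per pixel (default 1 px²).  Per-pixel
subtraction is mathematically equivalent, for the sum, to subtracting
from histogram bin values.  3-D stacks are max-projected first.  The
synthetic fixture renders a rectangular "Gall" whose polygon corners
enclose exactly the signal pixels, so noise-free recovery is exact; a
general polygon is rasterised with scikit-image and recovery is then
approximate at the boundary pixels.

## Numerical and design notes

- Wrap implemented as `mod 360` then shift; `wrap(−180°) = 180°`.
- Permutation assignments are drawn by row-wise `argsort` of uniforms —
  uniform over fly subsets at fixed group sizes.
- The simulator integrates the error recursion at the policy grid and
  fills 200 Hz samples linearly within each held interval; with 200 Hz
  not a multiple of 60 Hz, sample-to-interval assignment is by floor of
  `t × 60`.
- Flights always span the configured duration; early termination is not
  modelled, so the completion rule is exercised through hand-built traces
  in the tests rather than the generator.
- Degenerate inputs error loudly (empty headings, empty groups, shared
  flies, out-of-bounds ROIs, self-intersecting polygons) rather than
  returning sentinel values.

## Problem sizes

Simulation-based checks use 30 s flights (10–25 flies per group, 200
replicate cohorts for calibration/coverage, 50 for power); the cohort
contrast in `scripts/acceptance.py` runs at the full trial scale — two
5-minute 200 Hz flights for each of 20 flies per group — with 10,000
permutations and 10,000 bootstrap resamples.  These sizes were chosen so
the whole battery runs comfortably on a laptop core; the statistical
structure (per-fly goals, two flights per fly, fly-level resampling) is
identical at every scale.

## Known limitations

- The white-noise proportional controller cannot reproduce the long-time
  heading autocorrelation of real flights; per-flight ρ values should not
  be read as calibrated to any real genotype.
- The percentile bootstrap is first-order: with few flies (< ~10) its
  coverage can fall noticeably below nominal.
- The permutation test assumes group labels are exchangeable across flies
  under the null; fly-level covariates (age, batch) are not modelled.
- Stop annotations are trusted input; no stop detection from wing
  signals is attempted.
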