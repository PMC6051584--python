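# Methods

## The survey-design problem

A passive acoustic survey declares a site unoccupied only after enough
silent nights that a false absence is unlikely. Two quantities control the
calculation: the nightly detection probability *p* (which depends on season
stage, local density, and how much of the night is recorded) and the number
of survey nights *n*. The package estimates *p* from detection histories
with a single-season occupancy model, then inverts the cumulative detection
probability `P = 1 − (1−p)^n` for the smallest *n* reaching a stated
confidence. The threshold is inclusive (`≥ C`) with an integer ceiling; this
convention reproduces, for every one of the 30 published (p, nights) triples
in the reference design table, both printed night counts exactly — including
the boundary-proximity cases p = 0.274 at 80% (n = 5 falls just short) and
p = 0.778 at 95% (n = 2 gives 0.9507).

## Occupancy likelihood and its edge cases

The zero-inflated binomial likelihood is maximised on (logit ψ, logit p)
with BFGS from (0.5, 0.5), polished by Nelder–Mead; Wald standard errors
come from the central-difference observed information via the delta method.
Invalid (outage) nights simply reduce each site's exposure K_i — the
constant-p likelihood needs no balanced design and nothing is imputed.
Three regimes are handled specially:

- **All sites detected.** ψ̂ = 1 is forced onto the boundary and
  p̂ = Σd_i / ΣK_i is the exact binomial MLE; both are returned in closed
  form (no optimiser round-off), flagged `boundary`, with ψ's SE from the
  profile-likelihood half-width at a log-likelihood drop of 1.92 (the Wald
  SE diverges at the boundary).
- **Interior estimates driven past |logit| = 10** are reported as exact 0/1
  with profile-likelihood SEs for the same reason.
- **All-zero histories** leave (ψ, p) unidentifiable and are returned
  flagged `degenerate`; the design table records the failure in that row's
  `note` and continues.

A brute-force 1001×1001 grid search over (ψ, p) serves as an independent
oracle in the tests: on small histories the fitted log-likelihood must reach
the grid maximum to within 1e-6.

## Synthetic event streams

The generator emulates a season of field recordings as an inhomogeneous
Poisson process, `λ(site, t) = base_rate × diel(bin) × seasonal(week)`, with
both curves normalised to peak 1 so `base_rate` is bellows/hour at the joint
peak. Events are drawn per sunset-anchored hour bin (bins −12..+11 tile each
solar day), which makes the realised diel distribution match the curve by
construction — verified by a χ² goodness-of-fit property at n ≥ 10⁴ events.

Default study conditions: ten sites spanning densities 0–7.19 koalas/ha with
night-block bellow rates 0.03–8.89/h, August through January. The diel curve
sits at 0.02 through daylight, rises linearly from three hours before sunset
to a peak of 1.0 four hours after, and decays to 0.05 by ten hours after.
The seasonal curve is 0.3 through August/September, rises linearly through
October to a peak of 1.0 in the week of 25 November, and declines to 0.6 by
end of January. Site `base_rate` is set at twice the target night-block mean
because, averaged over the default curves, the 20:00–02:00 block runs near
half the joint peak rate. Female vocalisations are an independent
presence-only process (one marked event on ~3% of nights at low density,
~60% at high density) and never enter the occupancy analysis. Weather
outages are drawn uniformly subject to two caps (default ≤ 9 total days and
≤ 3 consecutive days per site).

What the generator does **not** emulate: recorder failure modes distinct
from weather (all outages are interchangeable), between-night correlation in
calling (every bin is independent Poisson), koala movement or identity, and
any geographic variation in the curves. Passing tests therefore show the
pipeline recovers the structure this process encodes — not that real
deployments will match its rates.

## Schedules, histories, conventions

The field schedule is five minutes at the top of each hour 02:00–19:00 plus
a continuous six-hour block from 20:00. Sub-sampling schedules select
minutes of that block: the full 6 h; the first 30 min of each block hour;
and 3 h / 2 h / 1 h windows centred on the empirical peak hour, 23:00–00:00
(about four hours after a typical ~19:00 sunset) — so the nested set
one ⊂ two ⊂ three ⊂ six gives cell-wise monotone detection, a property the
tests enforce. Clock placement of the peak windows and the choice of *first*
half-hours are genuinely open design points; both are configurable via
`Subschedule`. Windows are half-open `[start, start+duration)`; a night is
keyed by the date its 20:00 block starts (a 01:30 bellow belongs to the
previous date's night); the local clock is treated as continuous (no DST
arithmetic), matching how field timestamps are usually logged.

## Sunset and activity profiles

Sunset uses the standard NOAA solar-geometry formulas (zenith 90.833°) at
minute resolution, with the UTC offset defaulting to `round(longitude/15)`;
a per-date sunset table can override it. Latitudes beyond ±66° are rejected.
Diel profiles pool the 5-minute systematic samples by hour-from-sunset bin
and standardise to per-site proportions (sites differ ~300-fold in bellow
count); weekly profiles use mean bellows per night hour per week, with sites
under 225 total bellows excluded as noise-dominated.

Smoothing is a P-spline: cubic B-splines on uniform *unclamped* knots with a
difference penalty on adjacent coefficients, solved as augmented least
squares (QR) for numerical stability at extreme penalties. Uniform knots
make the order-2 penalty's null space exactly the straight lines, so the
λ→∞ limit is ordinary weighted least squares. λ is chosen by GCV over a log
grid (10⁻⁶–10⁸) when not supplied. The "increasing variability away from
sunset" in real profiles is accommodated by user-supplied observation
weights (default 1/(1+|x−x̄|) style weighting is left to the caller);
reported R² is unadjusted 1 − RSS/TSS on the weighted scale, defined as 0
for a constant response. R² from real data depends on the (unknowable)
variance structure of the original analysis and is deliberately not a
reproduction target.

## Detection distance

Received level is modelled as `source − s·log₁₀(d) − a·d` (s = 20 dB/decade
is spherical spreading; a absorbs vegetation/atmospheric excess
attenuation). The detection radius is where level no longer *exceeds* the
ambient floor (42 dB default), optionally minus a margin: a 75 dB source
under pure spherical spreading would cross 42 dB near 45 m, yet field
detections at ~100 m are typical because spectrogram inspection works below
the broadband ambient level — a ~7 dB margin reconciles the two. This is a
reporting convention, not asserted physics. Effective area is πr²/10⁴ ha
(100 m → 3 ha). Habitat contrasts are compared with a paired t-test at
matched distances; identical profiles return (t = 0, p = 1) and a constant
non-zero offset with zero spread is rejected as degenerate rather than
reported as t = ∞.

## Statistical comparisons

The one-way ANOVA and Pearson correlation helpers are thin wrappers over
scipy with explicit degrees of freedom. Note two documented quirks of the
reference tables: grouping the 15 low-density p̂ values by schedule gives
5 groups of 3, hence df (4, 10) — the matching F of 0.698 confirms those df,
and they are reported correctly here; and the ten-site density versus
bellow-rate correlation computed from the printed columns is r ≈ 0.87, which
is what the package (and its tests) report.

## Problem sizes and determinism

Simulation-backed checks use one season × ten sites (≈40k events) per seed,
20 seeds for the design-table structure study, 100 replicates of
100 sites × 8 nights for parameter recovery and Wald coverage, and 1000
replicates for the paired-test type-I study — sizes at which each suite runs
in seconds while keeping Monte-Carlo error well inside the asserted bands.
All randomness flows from one root seed through spawned child streams, so
every stage (and the whole pipeline) is bit-reproducible; identical seeds
give byte-identical output files.

## Known limitations

Constant-(ψ, p) models only (no covariates, no multi-season dynamics); the
10-site reference design cannot identify covariate effects anyway. The
simulator's curves are stand-ins with the published qualitative shape —
their exact values are free parameters exposed in `ActivityShape`. Density
enters only as a class threshold (1 koala/ha) and a rate scale; no
distance-sampling or acoustic-density estimation is attempted.
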