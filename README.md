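# pamsurvey

Survey-design analysis for passive acoustic monitoring (PAM) of vocalising
species, built around the southern koala (*Phascolarctos cinereus*) as the
worked case: male koalas advertise with low-frequency "bellows" whose rate
varies strongly with hour-from-sunset, week of the breeding season, and
local population density. The package answers the planning question PAM
practitioners actually face — *how many nights must a recorder run, on what
nightly schedule, to be confident a silent site is truly unoccupied?*

It is aimed at ecologists and biostatisticians designing autonomous-recorder
deployments, and at anyone wanting a reproducible, testable version of the
occupancy-based effort calculation.

## The model

Detection data are site × night binary histories. The constant-parameter
single-season occupancy model treats site *i* as occupied with probability
ψ; given occupancy, each of its *K<sub>i</sub>* valid nights is an
independent detection with probability *p*:

```
L(ψ, p) = Π_i  ψ p^{d_i} (1−p)^{K_i−d_i}        if d_i > 0
               ψ (1−p)^{K_i} + (1−ψ)             if d_i = 0
```

Fitting is by maximum likelihood on the logit scale (Wald SEs from the
observed information; boundary fits such as ψ̂ = 1 are solved in closed form
with profile-likelihood SEs). Survey effort follows from the cumulative
detection probability over *n* nights,

```
P = 1 − (1−p₁)(1−p₂)…(1−pₙ),
```

inverted for the smallest *n* with `1 − (1−p)^n ≥ C` at confidence C (80% or
95%).

Around that core sit: an inhomogeneous-Poisson bellow simulator with rate
`base_rate × diel(hour from sunset) × seasonal(week)`, recording-schedule
machinery (a 6-h night block 20:00–02:00 plus hourly 5-min samples, with
nested sub-sampling schedules of 6 h / 6×30 min / 3 h / 2 h / 1 h),
NOAA-style sunset geometry, penalized B-spline (P-spline) smoothing of
activity profiles, and sound-attenuation utilities for detection radius and
effective sampled area (πr² / 10⁴ ha).

## Worked example

Simulate a full breeding season at the ten built-in sites (densities
~0–7.2 koalas/ha), stratify by season stage and density class, fit the
occupancy model per stratum × schedule, and print the design table:

```python
import pamsurvey as pv

bundle = pv.run_pipeline(pv.PipelineConfig(seed=42, out_dir="out"))
for r in bundle["design_rows"]:
    if r.season_stage == "early" and r.schedule in ("six_hours", "one_hour"):
        print(f"{r.density_class:4s} {r.schedule:10s} "
              f"p={r.p_hat:.3f} n80={r.nights_80:.0f} n95={r.nights_95:.0f}")
```

```
high one_hour   p=0.853 n80=1 n95=2
high six_hours  p=1.000 n80=1 n95=1
low  one_hour   p=0.301 n80=5 n95=9
low  six_hours  p=0.639 n80=2 n95=3
```

Reading: at high-density sites one or two nights of recording suffice for
95% confidence in an absence under any schedule, while at low-density sites
in the early season a one-hour nightly schedule needs 9 nights versus 3 for
the full six-hour block. The effort arithmetic itself is one call:

```python
>>> pv.nights_required(0.385, 0.95)
7
```

i.e. at a nightly detection probability of 0.385, seven nights are needed
before an all-silent record gives 95% confidence the site is unoccupied.

The same stages are available from the shell:

```sh
pamsurvey simulate --seed 42 --out events.csv
pamsurvey schedule --events events.csv --schedule one_hour --out history.csv
pamsurvey occupancy --history history.csv
pamsurvey run-all --seed 42 --out out/
pamsurvey check-table3
```

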