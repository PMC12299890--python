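# Methods

## Problem setting

In a destructive/staggered rodent design, serum is drawn from each animal
on only part of the time grid (here: three rats at 0, 0.25, 0.5, 1, 1.5,
12, 24 h post-dose; three at 2, 4, 8, 36, 48 h), and the assay reports
concentrations below its limit of quantification (LOQ) as BLQ, i.e.
0 mg/L. The package performs noncompartmental analysis (NCA) on such data:
per-subject parameters where a subject's own grid allows them, and
group-level parameters from a pooled mean profile where it does not.

## Estimators

**Cmax/Tmax.** The maximum *observed* concentration and its sampling time;
ties are broken toward the earliest time, and times are compared exactly
(no tolerance merging). No interpolation — with 5–7 samples per animal any
interpolated peak would be model-dependent.

**AUClast / AUMClast (linear trapezoid, BLQ-as-zero).** Integration starts
at the subject's first *sampled* time — no concentration is imputed at
t = 0 for animals first bled at 2 h; whether to impute is an analysis
decision, not an I/O one, and the default is not to. BLQ samples enter as
concentration 0, and the window extends through the **first BLQ sample
after the last quantifiable point**, then stops; segments with both
endpoints BLQ contribute nothing. This specific rule is not a free choice:
it is the unique simple trapezoid scheme consistent with the reference
per-rat exposure values the test suite reproduces (40.78, 38.63, 29.7,
11.4, 25.3, 22.6 mg·h/L), and it has a physical reading — the curve is
taken to reach zero somewhere before the first BLQ sample, and the
triangular segment down to it is the least-assumption closure. Two
alternatives are provided behind `blq_rule`: `drop_blq` (quantifiable
points only) and `loq_half` (BLQ → LOQ/2, a common censoring convention).
AUMClast integrates t·C(t) with the same rule over the same window.

**Terminal rate constant K (lambda-z).** Ordinary least squares of ln C on
t over quantifiable, positive concentrations. Three selection modes:

- `auto` (default): among all contiguous runs ending at the last
  quantifiable point and starting at or after Tmax, pick the run with the
  highest adjusted R² = 1 − (1 − R²)(n−1)/(n−2). Runs need n ≥ 3 wherever
  one exists, because adjusted R² is undefined at n = 2; a 2-point run is
  used only as a last resort. Ties go to the longer run. A selection whose
  slope is ≥ 0 (no decline) yields a *flagged* fit with K unset, and the
  pipeline returns a partial result (Cmax/Tmax/AUClast) rather than
  raising.
- `window`: user-specified [start, end] hours.
- `fixed`: K supplied directly. This mode exists because published
  per-animal K values frequently cannot be re-derived from the printed
  concentrations — in the bundled study no contiguous log-linear window
  reproduces any of the six reported K values (one rat's terminal
  quantifiable segment even rises), so those values are treated as fixed
  inputs when reproducing the published tables, and the divergence of the
  automatic selector from them is expected and documented rather than
  hidden.

**Derived chain.** T0.5e = ln2/K with ln2 at full precision
(0.693147…; the truncated literal 0.693 is available as
`ln2_constant=0.693` for matching legacy reports). MRT = 1/K by default —
the single-compartment terminal-phase identity, and the definition under
which the bundled study's reported MRT values are internally consistent
(e.g. 1/0.01387 h⁻¹ = 72.1 h). The moment estimator AUMClast/AUClast is
available as `mrt_method="aumc_auc"`; it is the better estimator when the
observed window covers most of the curve, but differs materially under
heavy tail truncation. Vd = dose/(K·AUClast) and CL = K·Vd; with dose in
mg and AUC in mg·h/L these are liters and liters/hour *per animal*, not
per kg — the dimensional reading under which the bundled study's values
check out.

**Pooled mean profile.** Union of all sampled times; at each time the
arithmetic mean over the subjects actually sampled there, BLQ as 0. A
pooled point is BLQ only if every contributor was. `rounding_dp=2` rounds
the means before integration: reports that tabulate 2-dp means and then
integrate those get 23.47 mg·h/L for the bundled study where unrounded
means give 23.50; the switch defaults to off (full precision) and is set
explicitly when reproducing such tables. The pooled dose is the mean
subject dose.

**Group summaries.** Mean, SEM = s/√n (n−1 denominator), and the
symmetric Student-t interval mean ± t(1−α/2, n−1)·SEM. At n = 3 the
t-quantile (4.3027) is nearly double the normal one — using z here is a
common error this module deliberately avoids; a normal-quantile option is
not offered. CI bounds are never truncated at zero: a negative lower bound
for a nonnegative quantity is reported as computed, since it faithfully
reflects the uncertainty at n = 3.

**Rounding.** Internal values are full precision everywhere; report
writers round half-away-from-zero (38.625 → 38.63), matching how printed
tables round, via decimal arithmetic on the shortest float representation.

## Synthetic data generator

The simulator embodies standard one-compartment kinetics with first-order
oral absorption (the Bateman curve) plus an optional zero-order endogenous
input from a zero baseline:

    C(t) = F·D·ka/(Vd·(ka−ke))·(e^(−ke·t) − e^(−ka·t)) + R0/(Vd·ke)·(1 − e^(−ke·t))

with the ka = ke degeneracy replaced by its analytic limit
F·D·ka·t·e^(−ka·t)/Vd. Observation noise is multiplicative lognormal,
C·exp(ε), ε ~ N(0, σ), σ = √ln(1+cv²) — multiplicative so simulated
concentrations stay nonnegative, mirroring assay CVs. Values below the LOQ
are recorded as BLQ/0, exactly as an assay table would report them, not
dropped.

Defaults (per-parameter, with units):

| parameter | default | unit | why |
|---|---|---|---|
| dose_mg | 3.92 | mg | 10 mg/kg × 392 g typical adult male rat |
| ka_per_h | 0.9 | 1/h | with ke gives tmax ≈ 1.5 h |
| ke_per_h | 0.5 | 1/h | terminal t½ ≈ 1.4 h at the individual level |
| vd_L | 0.31 | L | scales the peak to ≈ 6 mg/L |
| bioavail_frac | 1.0 | — | F and Vd are confounded in an oral-only design |
| endo_rate_mg_per_h | 0 | mg/h | baseline serum signal is BLQ in the reference data; the term is available for sensitivity studies |
| loq_mg_per_L | 0.1 | mg/L | makes the curve unquantifiable by 12 h |
| noise_cv | 0.2 | — | typical GC serum assay variability |

These were fixed once from the closed-form identities tmax =
ln(ka/ke)/(ka−ke) and C(tmax) = F·D·e^(−ke·tmax)/Vd so that the noise-free
curve visually mimics the bundled study's mean profile (peak ≈ 6 mg/L near
1.5 h, BLQ from 12 h); they are illustrative, **not** estimates fitted to
the animal data.

What the generator does *not* emulate: absorption-phase irregularities
(double peaks, lag times), inter-occasion variability, enterohepatic
recirculation, a nonzero endogenous baseline (unless R0 is set), or
correlated assay errors. Passing recovery tests therefore demonstrates
estimator correctness under the stated model, not robustness to those
features of real data.

## Recovery experiments

`recovery_experiment` simulates replicate profiles on a grid, runs the
full pipeline per replicate, and reports bias and RMSE of K̂, AUClast and
Cmax against analytic truth (ke; the exact integral of the noise-free
curve over the grid span; the noise-free peak). Reference behaviour at the
defaults: a noise-free 30-point grid to 10 half-lives recovers ke within
1% and the AUC within 2% of the analytic integral (the residual being the
trapezoid's discretization error, shrinking quadratically with the grid);
under 20% lognormal noise the K̂ distribution over 200 replicates is
centred on ke within Monte-Carlo error. The mean AUC under lognormal noise
carries the expected +cv²/2 shift (the noise is median-, not
mean-preserving). On the sparse censored study grid (2–48 h, LOQ
0.1 mg/L) only three quantifiable points remain, still contaminated by
absorption, and K̂ is biased low by ~17% — quantifying the caution
required when reading per-animal terminal parameters from designs this
sparse. Problem sizes (30-point grids, 200 replicates) keep each
experiment in the seconds range while leaving Monte-Carlo error well below
the effects being measured.

## Numerical and degenerate-input policy

- Times must be strictly increasing per subject; duplicate
  (subject, time) pairs are rejected at read time, naming the pair.
- An all-BLQ profile yields Cmax = 0 at the first time with a warning, an
  AUClast of 0, and an incomplete result — never an exception.
- Fewer than 2 points cannot be integrated; fewer than 2 positive
  quantifiable points cannot support lambda-z (errors in both cases).
- `ka ≈ ke` (relative difference < 1e-9) switches to the analytic limit
  expression; the curve is continuous across the switch.
- CSV round-trips are lossless: floats are written in shortest
  round-trip representation and read with `float_precision="round_trip"`.
- Seeded `numpy.random.Generator`s drive all randomness; identical
  (parameters, design, seed) reproduce datasets byte-for-byte.

## Known limitations

- No compartmental model *fitting*: the simulator's model is for data
  generation and validation only.
- The automatic lambda-z selector is deterministic but, like all best-fit
  window rules, subject to selection effects at high noise; fixed-window
  mode is preferable when the terminal phase is known.
- Single-dose only; no accumulation/steady-state machinery.
- Vd and CL are apparent (oral) quantities — F is not separable from an
  oral-only design.
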