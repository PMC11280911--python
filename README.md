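# dfapower

Tools for relating **cycling power** (external load) to the **short-term
scaling exponent of heart-rate variability, DFA-a1** (internal load),
from everyday workout recordings: RR intervals from a chest strap plus
power-meter data, no lab test required.

## The science in brief

DFA-a1 is the slope of `log F(n)` vs `log n` from detrended fluctuation
analysis of the RR series over box sizes of 4–16 beats. At rest, healthy
RR dynamics are fractal (a1 ≈ 1.0); with rising exercise intensity the
exponent falls monotonically through ≈ 0.75 (a proxy of the aerobic
threshold) and ≈ 0.5 (uncorrelated dynamics, a proxy of the anaerobic
threshold) and below. Pairing a rolling 120-s DFA-a1 (recomputed every
5 s) with the mean power over the same window gives a (P, a1) point
cloud whose negative relationship encodes the athlete's intensity zones.

Raw point clouds are noisy, mainly because the cardiac response *lags*
power: a hard burst yields points with high power but still-high a1, and
the recovery yields the mirror image. The **representative method**
mitigates this: slice the a1 axis into equal-width intervals (8 bins up
to a1\* = min(1.2, a1_max) per workout; 9 dynamic-range bins plus 5
upper bins up to min(1.8, a1_max) for pooled 10-day workout groups),
average each sufficiently populated interval into one representative
point (≥ 8 points per bin for workouts, ≥ 10 for groups), and correlate
or fit the representatives instead of the raw cloud.

Workout groups (all of a user's quality-passing workouts within 10 days,
minimum 4) are fitted with two two-parameter laws,

    P = m · a1 + q        and        P = s / a1 + t ,

by least squares, and the better fit — only if its R² exceeds 0.75 — is
evaluated at a1 = 1.0, 0.75, 0.5 to produce threshold-power estimates.
Monitoring context comes from the External Stress Score (ESS; one hour
at the threshold setting ≡ 100) and the power-to-HR ratio over minutes
5–20, both tracked as 10-day rolling means.

Quality gates applied to each workout, in order: ≤ 5% RR artifacts
(detected against a local median, corrected by split/merge/spline);
only minutes 5–20 kept; ≥ 90% of kept samples pedaling (then zero-power
samples dropped); ≥ 50% of remaining samples in the dynamic range
(a1 < 1.0).

## Worked example

Everything is exercisable on synthetic data with known ground truth
(the generator drives a scheduled-spectrum fractal RR process through a
lagged power→a1 law; see `docs/methods.md`):

```
dfapower simulate --out-dir data --seed 7 --n-users 1 --workouts-per-user 5 --days-span 8
dfapower analyze-cohort data --out-dir out
```

prints `1 groups from 5 passing workouts`, and `out/groups.json`
contains (generated with ground truth m = −250, q = 420, 30-s lag,
2% artifacts):

```
correlations: r_standard_total -0.902, r_representative_dynamic -1.0
linear fit:      m = -216.3, q = 401.9, R² = 0.99   <- selected (gate 0.75)
hyperbolic fit:  s = 61.4,  t = 145.3, R² = 0.82
thresholds: P(a1=1.0) = 185.6 W, P(0.75) = 239.7 W, P(0.5) = 293.8 W
```

The representative correlation (−1.0) is stronger than the standard
all-points correlation (−0.90), the linear law wins the best-fit rule,
and the threshold powers are ordered P(0.5) > P(0.75) > P(1.0) as a
decreasing law requires. `out/trend.csv` holds the dated threshold
estimates with 10-day rolling ESS and power-to-HR context.

Single workouts follow the same path via
`dfapower analyze-workout <dir>`; a workout rejected by the quality
gates still produces a report with `passed: false` and the failing
criteria.

## Layout

* `workout_io` — CSV/JSON interchange (`rr.csv`, `power.csv`, `meta.json`)
* `preprocess` — artifact detection/correction, smoothness-priors detrending (λ = 500)
* `dfa_windows` — windowed short-term DFA (boxes 4–16, 120 s / 5 s grid)
* `cohort` — the four quality gates and 10-day grouping
* `representatives` — segmentation, representative points, Spearman variants
* `models` — linear/hyperbolic fits, best-fit gate, threshold powers
* `monitoring` — ESS, power-to-HR, rolling trends
* `synthetic` — ground-truth workout/cohort generator
* `cli` / `pipeline` — orchestration and the `dfapower` command
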