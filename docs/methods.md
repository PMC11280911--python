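# Methods

This note documents the models and procedures implemented in
`dfapower`, the parameter choices that matter, and what the synthetic
test bed does and does not establish about real data.

## Signal model and analysis chain

The package treats a workout as two time-stamped streams: interbeat (RR)
intervals in milliseconds and cycling power in Watts (nominally 1 Hz).
The analysis chain per workout is fixed:

1. artifact detection/correction on the raw RR series;
2. smoothness-priors detrending of the corrected series;
3. rolling short-term DFA (a1) on 120-s windows every 5 s, paired with
   the 120-s mean power on the same grid;
4. quality gates; then segmentation into a1 intervals, representative
   points, correlations, and model fits on pooled 10-day groups.

### Artifact handling

Consumer HR straps produce long/short/missed/extra/ectopic beats. A
beat is flagged when its RR deviates from the median of a centred
11-beat window by more than `max(20 ms, 0.25 × median)`. Flagged beats
are classified greedily left to right: an interval close to twice the
local median is treated as a missed beat and split in half (a beat is
inserted); two adjacent flagged intervals summing to one plausible
interval are merged (an extra detection removed); everything else is
replaced by cubic-spline interpolation over unflagged neighbours. The
artifact fraction is counted *before* correction and is the quantity
the 5% quality gate sees. The window/threshold defaults reproduce the
qualitative behaviour of the artifact filters customary in HRV
software while remaining fully specified and testable; exact
replication of any proprietary implementation is a non-goal.

### Detrending

Slow trends (drift of mean HR with intensity) would contaminate the
fluctuation analysis, so the corrected series is detrended once per
workout with the smoothness-priors method: the trend solves
`(I + λ² D₂ᵀD₂) τ = z` with `D₂` the second-difference operator on the
beat index, and the residual `z − τ` is analysed. λ = 500, the
conventional value for exercise HRV. Limits are exact: λ = 0 returns a
zero residual, constants and straight lines lie in the penalty null
space, and as λ → ∞ the trend converges to the OLS line (verified
numerically up to λ = 1e5; beyond that the normal equations become too
ill-conditioned for float64, which is far outside the useful range).
The sparse system is solved directly; the solve is exact to solver
round-off (~1e-10 relative).

### Short-term DFA and the finite-box correction

DFA-a1 follows the classic formulation: mean-centre, integrate,
partition into non-overlapping boxes of n = 4…16 beats counted from the
segment start (remainder discarded), least-squares line per box, RMS
fluctuation F(n), and a1 = OLS slope of log F(n) vs log n (natural
log, all 13 integer scales).

At boxes this small, first-order DFA is biased: for uncorrelated data
`E[F²(n)] = σ²(n² − 4)/(15n)` exactly (we verified this closed form by
simulation), not ∝ n, which drags the 4–16 slope of white noise up to
≈ 0.58. Since the physiological reference points of the method (1.0
fractal, 0.75, 0.5) are defined on the theoretical exponent scale, the
estimator divides each F(n) by the exact finite-box factor
`sqrt(1 − 4/n²)` by default. White noise then reads 0.500 in
expectation; integrated noise reads ≈ 1.42 rather than the asymptotic
1.5, and 1/f noise reads ≈ 0.93 in 150-beat windows — the correction
is exact only for uncorrelated data, and no single parameter-free
convention removes the signal-dependent finite-scale transfer
entirely. The correction is a config switch (`bias_correction`), and
every windowed estimate inherits it consistently, including the
synthetic generator's calibration, so all internal comparisons are
convention-matched.

Windows are trailing, with half-open membership `(t_end − 120, t_end]`,
on the grid `t_end = 120, 125, …`. A window needs ≥ 32 beats (two boxes
at the largest scale) and non-zero variance; otherwise the sample is
marked invalid rather than raising.

### Quality gates (fixed order)

1. artifact fraction ≤ 0.05;
2. crop to `t_end ∈ [300 s, 1200 s]` (strap settling / fatigue);
3. pedaling fraction (share of cropped samples with P > 0) ≥ 0.90,
   then zero-power samples are discarded;
4. dynamic fraction (share of remaining samples with a1 < 1.0) ≥ 0.50.

The order matters: the dynamic fraction is evaluated after zero-power
discard, and a regression test pins this. Rejected workouts contribute
nothing downstream but still produce a report with the failing tags.

### Segmentation and representatives

Single workout: 8 equal-width bins on `[a1_min, a1*]`,
`a1* = min(1.2, a1_max)`, minimum 8 points per representative. Group:
9 equal-width bins on `[a1_min, 1.0]` plus 5 on `[1.0, min(1.8, a1_max)]`,
minimum 10. Bins are half-open `[lo, hi)` with the last bin of each
region closed; points above a1\* are excluded from representatives but
kept in the all-points correlation. Representatives carry arithmetic
means and sample (n−1) SDs of both coordinates. A conservation
property holds by construction: with every bin populated, the
count-weighted mean of representative powers equals the overall
in-range mean power.

Correlations are Spearman (average ranks, asymptotic p-values):
all points, dynamic-range points (a1 < 1.0), dynamic representatives,
and — for groups with upper-region representatives — all
representatives. Variants with < 3 points or zero rank variance are
reported absent with a tag. Size labels follow the conventional bands
(0.3 ≤ |r| < 0.5 low, 0.6 ≤ |r| < 0.8 moderate, |r| ≥ 0.8 high); values
in the unlabelled gap [0.5, 0.6) are reported "unclassified" rather
than forced into a band.

### Model fits and threshold powers

`P = m·a1 + q` and `P = s/a1 + t` are both linear in their parameters
(the hyperbola via the 1/a1 transform), so both are fitted by exact
least squares — no iteration. R² is computed in the original power
space for both, making the "R² nearest 1" comparison like-for-like.
Ties prefer the linear model (the simpler interpretation). Threshold
powers at a1 = 1.0 / 0.75 / 0.5 are emitted only when the winning R²
exceeds 0.75; by default fits use all representatives (a config switch
restricts to the dynamic region).

### Monitoring

ESS = Σ over ≤ 10-min steps of `sec_step/3600 × i_step² × 100`, with
`i_step = (mean(moving_av(power)⁴))^¼ / thresh` and a 30-s trailing
rolling average that restarts inside each step (steps exist precisely
to restore additivity in time of the fourth-power weighting; leakage
across step boundaries would reintroduce the non-linearity). Recording
gaps are skipped, not zero-filled — zero-filling would conflate gaps
with coasting. One hour at `thresh` gives exactly 100. The power-to-HR
ratio uses the artifact-corrected (never detrended) RR over minutes
5–20. Rolling 10-day trends average over the observations present in
the trailing window (days without workouts do not dilute the mean);
threshold-power trend points are anchored at group end dates.

## Synthetic data generator

The generator emulates the assumed data-generating structure, not full
cardiac physiology. Power profiles (steady, staircase, intervals,
ERG-like ramps) are rendered at 1 Hz, passed through a first-order
exponential filter (default time constant 30 s) representing cardiac
lag, and inverted through a ground-truth linear law (defaults
m = −250 W, q = 420 W) into a clamped a1 target. RR is
`rr_mean(t) + rr_sd · x(t)` with x(t) Gaussian noise synthesised
spectrally (`S(f) ∝ f^−β`) in 64-beat blocks with 50% overlap and
sine-envelope cross-fading, the local β scheduled per block.

Because the measured windowed a1 is not the asymptotic `(β + 1)/2` at
scales 4–16, the β realising a wanted a1 comes from a calibration map
built by brute force: constant-β series pushed through the package's
own detrend + windowed-DFA pipeline, 20 grid points on β ∈ [−1.0, 2.8],
monotonised and inverted by interpolation, cached per seed. The map
covers measured a1 ≈ 0.21–1.62, so the default clamp bounds are
0.3–1.4; targets outside the calibrated range raise.

Defaults are chosen for realism at endurance intensity: RR mean 400 ms
(~150 BPM; this also puts ~300 beats in each 120-s window, halving the
per-window a1 estimation noise relative to resting HR), RR SD 25 ms, a
weak RR–power coupling (0.08 ms/W) so detrending has a genuine trend
to remove, and a 2% artifact rate injected as missed/extra/ectopic
events whose *detected*-beat budget matches the nominal rate. RR
timestamps accumulate from the RR values, so series are physically
consistent. Everything is deterministic given a seed.

Default cohorts rotate six-level staircases (150–340 W, i.e. a1
targets ≈ 1.08 down to 0.32, mostly in the dynamic range with one easy
level feeding the upper region) and interval sessions, spread over 8
days so every user forms one valid 10-day group.

### What the synthetic bed shows — and does not

End-to-end on default cohorts, the pipeline recovers the ground-truth
(m, q) within 10% in gated groups, and interval workouts with cardiac
lag reproduce the central mechanism: the raw-cloud correlation
collapses (≈ −0.5) while the representative correlation survives
(≈ −0.9). Two caveats temper extrapolation to real data. First,
binning on the *measured* (noisy) a1 attenuates the fitted slope — an
errors-in-variables effect of a few percent here that any user of the
method inherits; with narrower intensity ranges or resting heart rates
it would grow. Second, the generator omits respiratory sinus
arrhythmia, HR drift/decoupling, device dropouts and power-meter
calibration error, so passing tests validate the pipeline's logic and
statistics, not the physiological fidelity of DFA-a1 itself.

## Problem sizes and numerical choices

Test and reference runs use desk-scale sizes: 1500–3000-beat series
(≈ 20–40 min), cohorts of 1–2 users × 4–6 workouts of 25 min, and five
independent realisations when averaging windowed DFA means (grid
windows overlap 96%, so fresh realisations, not more windows, tighten
the mean). Spearman oracles agree to 1e-12, the DFA implementation
agrees with an independent naive implementation to 1e-6 on matched
conventions, and the hyperbolic fit equals the transformed OLS exactly.
Degenerate inputs (constant segments, empty bins, < 3 points) are
reported as invalid/absent rather than raised wherever the pipeline
can continue.

## Known limitations

* The artifact detector is a local-median filter, not a
  waveform-level beat classifier; severely corrupted recordings should
  be excluded upstream.
* The finite-box correction is exact only for uncorrelated data;
  strongly correlated regimes read slightly low (1/f ≈ 0.93). All
  internal comparisons are convention-matched, but absolute a1 values
  from other software may differ by a few hundredths.
* Group segmentation assumes some dynamic-range data; users who never
  exceed a1 < 1.0 produce no usable groups (by design — such data
  cannot inform thresholds).
* Threshold-power trends inherit the user's `thresh` setting for ESS
  normalisation; changes of that setting between workouts are not
  reconciled.
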