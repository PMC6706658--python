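# Methods

## Model

The promoter is a two-state Markov switch: OFF → ON at rate `k_on`, ON → OFF
at rate `k_off` (both 1/s), with polymerase initiation a Poisson process of
rate `r` (1/s) gated by the ON state. Each polymerase occupies the gene for
the elongation time `T` (s), so the observable — what an MS2/MCP reporter
measures — is the number of nascent transcripts, a gated Poisson stream
filtered by a boxcar of width `T`. Stationary mean and variance are

```
<m>    = r T k_on / kappa                      kappa = k_on + k_off
Var(m) = <m> [ 1 + (2 r k_off / kappa^2) g(kappa T) ]
g(x)   = 1 + (exp(-x) - 1) / x
```

`g` maps [0, ∞) increasingly onto [0, 1), so the Fano factor
`Var/<m> = 1 + (2 r k_off / kappa^2) g(kappa T)` is always ≥ 1. Assumptions:
time-homogeneous rates (steady state), a fixed deterministic `T` per gene,
unit signal per polymerase, no mRNA-level (post-release) dynamics.

### Limits and sensitivities

With `x = kappa*T`: for `x ≫ 1`, Fano ≈ `1 + 2 r k_off / kappa^2`; the
derivative of that limit with respect to `k_off` carries the factor
`(1 − 2 k_off/kappa)` and changes sign at `k_on = k_off`, which is why the
Fano response to `k_off` is reported *indeterminate* in the fast-switching
regime. For `x → 0` the correction term behaves as `r k_off T / kappa`:
the often-quoted "Fano → 1" Poisson limit therefore requires this retained
first-order term to be small as well — shrinking `kappa*T` alone (e.g. by
lowering the switching rates at fixed `r`, `T`) leaves the Fano factor at
`1 + r T k_off/kappa`. The package's limit checks use parameter points where
the product is genuinely small (short residence times, or `r*T ≪ 1`), and
the monotone-convergence property test drives `T → 0` at fixed rates.

Regime labels used by the sensitivity table: `kappa*T < 0.1` small,
`> 10` large, ambiguous in between (the expansions are accurate to ~1%
outside those brackets); in the ambiguous band signs fall back to the exact
analytic derivatives.

### Matched-mean solving

Comparing conditions at a mean ratio α: `r` and `k_on` invert analytically
(`r₂ = α r₁`; `k_on` from the target occupancy `α·k_on/kappa`, infeasible at
occupancy ≥ 1), `k_off` by Brent root-finding on the closed-form mean
(monotone in `k_off`), verified by substitution to 1e-9 relative.

## Simulator

Promoter paths are exact: exponential dwell times with the current state's
rate; initiation events per ON interval drawn as a Poisson count with
uniform placement (an exact realization of the gated Poisson process).
The initial state is drawn from the stationary occupancy `k_on/kappa`, so
the promoter path is stationary from t = 0 and the nascent count from
t = T (the boxcar must fill); an optional burn-in exists for users who want
one. Stationary-sample helpers read each independent trajectory once at
t = T.

Observation model: `signal = (background + calibration·counts)·exp(−b·t) +
N(0, noise_sd)`, floored at 0 (the floor can be disabled for moment
checks). The polymerase contribution is a unit step over age ∈ [0, T) —
MS2 loops in the 5′UTR are transcribed essentially immediately; a linear
`ramp` alternative (3′-positioned loops) is available behind a flag.
Additive Gaussian noise is the minimal measurement-noise choice; its SD is
a config knob. Bleaching is multiplicative and defaults to 0 for
model-validation runs, where it would only exercise the correction step.

Defaults emulating the imaging conditions: frame interval 15 s, T = 120 s
(within the 1.6–2.5 min elongation estimate for reporters of this size),
1 h of observation, 200 nuclei. Per-cell RNG streams are spawned from one
root `SeedSequence`, so ensembles are reproducible and order-independent.

Paired-allele mode gives each cell a shared activation-time offset
(SD `extrinsic_onset_sd`) and each allele a private one
(SD `intrinsic_onset_sd`); the promoter is silent before its activation
time and starts ON at it (a sharp enhancer-driven switch-on, so the
assigned onset is crisp in the ground truth). `paired_onset_table`
generates the same structure directly as onset/end tables for
decomposition studies.

What the generator does *not* emulate: nuclear movement and tracking
failures (gaps must be injected manually), non-Gaussian background
structure, diffusion of released mRNA, cell division, embryo geometry.
Passing tests therefore validate the statistical machinery, not the imaging
chain upstream of trace extraction.

## Trace processing and burst calling

Two-pass baseline: fit the per-frame mean of all nuclei to a straight line,
classify nuclei against it, refit on the inactive nuclei only (fallback to
pass 1, with a warning, if none are inactive). The inactive-nuclei line
normalized to its t = 0 value, clamped to (0, 1], is the bleaching decay
fraction; when the fitted background at t = 0 is not positive there is
nothing to estimate bleaching from and the decay is pinned at 1.

Classification and burst calling use the median-filtered (window 3,
NaN-aware — gaps are preserved and break ON runs) signal, strictly above
1.2× the baseline, in runs of ≥ 5 frames, from 15 min into the record
(t = 0 is the start of nuclear cycle 14; input tables must already be
time-aligned). A run straddling the window start counts only its in-window
frames. Sub-minimum runs are dropped, never merged. Burst end is exclusive
(last ON frame + one interval) so durations, off periods and margins tile
the analysed span exactly. Amplitude is the mean of the median-filtered,
baseline-subtracted, bleach-normalized signal in the burst; "sustained"
means a burst > 10 min. All five thresholds are configuration, not
constants — they were set empirically for MCP-GFP movies.

Resolution floor: the nascent signal persists ~T after the promoter
switches off, so OFF gaps shorter than ~2 min are invisible; the test suite
asserts this as the expected limitation rather than pretending to recover
them.

## Empirical noise statistics and diagnosis

Preprocessing for noise statistics matches the burst pipeline: median
filter 3, baseline subtraction and bleach normalization where applicable,
then an analysis window (simulated data: t ≥ T, so the boxcar is full).

Fano factor: per-frame mean and total variance across traces; extrinsic
variance as the per-frame covariance across pairs (true allele pairs, or
non-overlapping adjacent traces as the neighbouring-nuclei proxy; self-pairs
reproduce the degenerate extrinsic = total check); intrinsic = total −
extrinsic; pooled as the ratio of time-summed intrinsic variance to
time-summed mean (a per-frame-average alternative is exposed). Negative
per-frame intrinsic values are retained in the arrays; a negative pooled
value clamps to 0 with a warning. Bootstrap (default 50) resamples whole
pairs, never frames; the Fano ratio pairs the two conditions' independent
replicate streams.

ACF: per trace, mean-subtracted products summed over valid frame pairs and
divided by the tracked-frame count (biased normalization), normalized at
lag 0, averaged across traces; bootstrap over traces. The decorrelation lag
is the linearly interpolated first crossing of a configurable level
(default 0.5).

Shift rule (the data judgement made quantitative): a shift requires the
decorrelation-lag difference to exceed both `shift_z` (default 2) joint
bootstrap SDs *and* half the ACF lag spacing. The floor matters: lags are
interpolated between frame-spaced samples, and systematic sub-frame
differences (e.g. doubling `r` slightly raises the promoter-noise share of
the variance and drags the interpolated crossing by 1–3 s on a 15 s grid)
are below what the sampled ACF resolves; without the floor they would be
"detected" at large n and misread as switching-rate changes. Only rightward
shifts are diagnostic; leftward differences are reported but not acted on.

Decision logic: FFRatio z = (ratio − 1)/SD against a cutoff of 2; right
shift → `koff_down` regardless of the ratio; otherwise significantly > 1 →
`r_up`, < 1 → `kon_up`, else ambiguous. `fast_dynamics` (in the
self-validation set from the known rates as `min(kappa)·frame_interval > 1`,
i.e. switching decorrelates within a frame) marks the ACF uninformative and
keeps `koff_down` as an alternative in either Fano-only verdict.

### Self-validation (signature study)

For each regime (slow `k_on = 0.01`/s, fast `k_on = 0.1`/s) and each
parameter, condition 2 is solved to double the mean through that parameter
alone, both conditions are simulated (200 cells × 1 h at 15 s/frame,
T = 120 s, r = 0.2/s, additive noise SD 1 AU; `k_off = k_on` for the
r-variation and `k_off = 3 k_on` for the switching-rate variations so the
occupancy doubling is feasible), and the full pipeline is run. Sizes were
chosen so the whole 12-ensemble study runs in a few seconds on one CPU
while leaving each verdict's bootstrap z well clear of its cutoff. Across
seeded replicates the correct parameter is recovered in a clear majority of
runs and every failure is an *ambiguous* verdict (typically the slow-regime
`k_off` case, whose ~10 s ACF shift occasionally dips under the resolution
floor), never a wrong definite parameter.

## Dual-allele variance decomposition

For onset (or end) times of cells with both alleles scored, with `mu` the
pooled mean over all 2n values:

```
total     = sum[(a - mu)^2 + (b - mu)^2] / (2(n-1))
extrinsic = sum[(a - mu)(b - mu)] / (n-1)
intrinsic = total - extrinsic = <(a - b)^2> / 2   (non-negative)
```

The consistent (n−1) normalization makes the decomposition an identity and
every component exactly invariant to swapping the arbitrary allele labels
within any subset of cells and to global time shifts. Cells with a silent
allele are excluded here but counted in the denominator of the
ever-both-active synchrony fraction; the onset-window synchrony fraction
(default window 5 min) is computed among both-active cells only. A minimum
of 3 complete pairs is enforced.

## Problem sizes and numerical choices

Simulation-versus-theory checks use 2000 independent stationary samples per
parameter point across `kappa*T ∈ {0.1, 1, 10}` with agreement required
within 3 bootstrap SDs; FFRatio experiments use 200 cells × 1 h per
condition with 50 trace-level bootstraps. Root finding uses Brent's method
at machine tolerance with a verified 1e-9 relative match; `g` and its
derivative switch to series below `x = 1e-6`; all rates are 1/s and times s
internally, with unit conversion only at the I/O boundary.

## Known limitations

No transient (pre-steady-state) moments or full copy-number distributions;
no likelihood-based inference of (r, k_on, k_off); no combination rule for
diagnoses across more than two conditions; the diagnosis assumes both
conditions share `T` and the processing chain; burst statistics inherit the
~2 min OFF-gap resolution floor; the two-pass active/inactive segregation is
run exactly twice (borderline traces could in principle oscillate under
further iteration).
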