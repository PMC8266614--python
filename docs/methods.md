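# Methods

## Dwell-time model

An observed binding event's duration is modeled as a draw from a K-component
exponential mixture (weights `a_k` on the unit simplex, lifetimes `τ_k > 0`),
conditioned on falling inside the observation window `[t_m, t_x]`:

```
f(t) = [ Σ_k (a_k/τ_k) e^(−t/τ_k) ] / [ Σ_k a_k (e^(−t_m/τ_k) − e^(−t_x/τ_k)) ]
```

The amplitudes in this truncated density are the *pre-truncation* mixture
weights: conditioning divides numerator and denominator by the same window
mass, so fitting recovers the weights of the underlying process, not the
(window-biased) fractions among detected events. Assumptions: events are
independent, each complex dissociates with a single first-order rate, and the
window is common to all events in a dataset.

Defaults: `t_m = 0.1 s` (one camera frame — the smallest interval that can
occupy a frame) and `t_x = 180 s` (the movie length). Both are parameters of
`ObservationWindow`, not constants.

## Synthetic-data generator

`simulate_dwells` emulates the generative process the fits assume, plus the
recording artifacts that real data carry:

1. component chosen with probability `a_k`, duration ~ Exponential(`τ_k`);
2. optional competing photobleaching: observed duration =
   min(binding, Exponential(`τ_bleach`)) — applied per event. Default off;
   173 s reproduces the Cy5 regime. This yields the closed-form property
   `1/τ_obs = 1/τ + 1/τ_bleach` used as a test oracle;
3. sub-resolution loss: raw durations `< t_m` are discarded *before*
   quantization, so the discard fraction equals `1 − S(t_m)` of the mixture
   exactly (a tested invariant);
4. frame quantization: survivors are rounded **up** to the next full frame —
   an event must occupy a frame to be seen. `frame_interval=None` disables
   quantization for idealized continuous sampling; the Kolmogorov–Smirnov
   agreement test against the analytic truncated CDF uses this mode, because
   0.1-s discretization alone moves the empirical CDF by ~0.03 near `t_m`,
   above the n=10000 KS critical distance (~0.017) — a discretization
   artifact, not a sampling defect;
5. window censoring: events outlasting `t_x` are dropped by default
   (`drop_incomplete`, consistent with a density normalized over the window);
   `cap_at_window` keeps them at `t_x` for sensitivity analyses.

Two consequences worth knowing. Left-truncation at `t_m` shifts the sample
mean of an exponential by exactly `t_m` (memorylessness), and ceil-rounding
adds about half a frame; both are visible in the generator's output and
asserted in tests. And fitting the continuous density to frame-quantized
data biases short lifetimes upward: at `τ = 2` frames (0.2 s) the bias is
roughly +25–30% (a dedicated test documents it); at `τ ≥ 5` frames it is
negligible relative to sampling error.

What the generator does **not** emulate: spot detection and drift, blinking,
flow dead time, aggregation, non-exponential (e.g. multi-step) dissociation,
and concentration-dependent rebinding. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
these real-data pathologies.

`simulate_decay` produces rifampicin-chase series as (target, reference)
signal pairs so the normalization step is exercised: first-order
`percent(t) = 100·e^(−ln2·t/t½)` or linear `percent(t) = 100 − (50/t½)·t`
(floored at 10⁻³%), with optional multiplicative Gaussian noise per channel
emulating gel-band quantification error.

## Event calling

Traces are binarized against a threshold; maximal bright runs (merging dark
gaps up to `gap_tolerance_frames`, default 0) become events of duration
(run length × frame interval), matching the simulator's quantization. The
default threshold is baseline + 3σ with baseline and σ estimated robustly as
the median and 1.4826×MAD of the whole trace: with the molecule unbound most
of the time these track the dark state, and unlike estimates from the
dimmest quantile of frames (whose truncated tail deflates σ and drops the
threshold to the baseline mean) they are stable against the bound-state
contamination. Events touching the final frame are censored per the same
policy as the simulator. Threshold monotonicity (lower threshold ⇒ at least
as many events, absolute rule) holds only while the baseline cannot bridge
two events across a gap frame; the property test stays in that regime.

## Maximum likelihood fitting

The negative log-likelihood is minimized over `(K−1)` weight logits
(softmax keeps weights on the open simplex) and `K` log-lifetimes with
L-BFGS-B and an analytic gradient, from 20 deterministic seed-derived starts
(lifetimes log-uniform over the window, weights Dirichlet(1)); bounds keep
`exp()` in range. Convergence: relative likelihood change ≤ 1e-12 and
gradient norm ≤ 1e-8 (configurable). Equal-likelihood starts resolve to the
lowest start index, fits are therefore bit-reproducible. Lifetimes are
reported ascending with weights permuted along, making component labels
comparable across fits and bootstrap replicates. Two fitted lifetimes within
5% of each other raise a "more components than resolvable" warning flag.

Model selection is by BIC over K = 1–3 (the generating K is recovered in
every simulated regime); K can also be forced per condition. BIC is a
pragmatic choice: candidate models are nested and the likelihood-ratio
statistic for an extra true component dwarfs the penalty at the sample sizes
used (a test checks this explicitly).

## Bootstrap and comparisons

Standard errors come from resampling events with replacement (1000 replicates
at full fidelity; tests and the analysis scripts use 60–400 to keep runtimes
in seconds — problem sizes chosen as the package's own trade-off), refitting
each replicate warm-started from the base optimum plus 3 random restarts, and
taking the σ of the replicate estimates after ascending-lifetime sorting.
Non-converged replicates are dropped and counted; >10% marks the summary
invalid. A per-molecule block bootstrap is available when within-molecule
dependence is suspected.

The residual amplitude of a three-component model gets the quadrature
propagation `σ_a3 = √(σ_a1² + σ_a2²)` *and* the direct bootstrap σ of
`a3`: the quadrature form assumes uncorrelated `a1`, `a2`, while the simplex
constraint induces strong anticorrelation (r ≈ −0.9 in the tested regime),
making propagation a conservative overestimate. Both numbers are reported.

Condition comparisons use `(A−B)/√(σ_A²+σ_B²)` with a standard-normal
reference by default (bootstrap σ treated as the estimator's standard
error); a Welch-t policy with user-supplied df is available since the
original test's degrees of freedom are not derivable from bootstrap output.

## Half-life estimation

Chase series are normalized as
`percent_i = 100·(target_i/reference_i)/(target_0/reference_0)` — invariant
to rescaling either channel. The first-order estimator is ordinary least
squares of `ln(percent)` on time ("exponential trendline" in the spreadsheet
sense), `k = −slope`, `t½ = ln2/k`, R² on the log scale; a direct nonlinear
exponential fit is available for comparison. The linear estimator is OLS of
percent on time, `k* = −slope` in %/min, `t½ = 50/k*` — the time to reach
50% by straight-line decline. `choose_method` selects first-order when its
log-scale R² ≥ 0.90 (a declared adequacy bar, not an inferred one),
otherwise linear. Non-negative slopes yield an explicit no-decay flag rather
than a meaningless half-life.

A caveat the analysis scripts surface deliberately: over a sampling window
shallower than one half-life, a straight line and an exponential are
statistically indistinguishable (a linear series spanning 100→60% has
log-R² ≈ 0.99; even 100→20% still gives ≈ 0.95), so the selector only
prefers the linear model once the series approaches zero. The slow-decay
analysis therefore chases past the half-life (0–20 min) while the fast
regime uses 0–8 min at 1-min steps.

## Numerical and degenerate-input choices

* Likelihood evaluation uses log-sum-exp; zero-weight components are skipped
  (they contribute nothing but would poison the log).
* A dataset of identical durations is legal for K=1: the MLE solves the
  truncated-mean equation and the bootstrap σ is exactly 0.
* Durations outside the window are a hard error listing the offending rows —
  silently clipping would bias fits.
* Fit guard: at least 10·K events (configurable) before attempting a fit.
* Zero/negative reference signals, times not starting at 0, and overlapping
  planted trace events are all rejected at construction with named fields.
* All randomness flows from explicit integer seeds; pipeline stages derive
  per-stage seeds from the global one, so a run is reproducible byte-for-byte
  (result documents contain no timestamps).

## Known limitations

* The continuous likelihood on quantized data biases lifetimes near the
  frame scale (documented above); a discrete-likelihood variant would remove
  it but is out of scope.
* Bootstrap refits warm-started at the base optimum can understate σ in
  multimodal likelihood landscapes; the 3 random restarts mitigate but do
  not eliminate this.
* The event caller does no blinking correction (`gap_tolerance_frames = 0`
  by default): a single dark frame ends an event.
* Right-censored events (still bound at movie end) are discarded, not used
  as survival information; with 3-minute movies and ≤60 s lifetimes the loss
  is ~5% of long events and the truncated normalization accounts for the
  selection, but a survival-likelihood treatment would be strictly better.
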