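# Methods

## The model

The package forecasts a scalar series x_1, x_2, … with an autoregression
whose coefficients are *coerced* to ±1:

    x_t = c + Σ_{i=1}^p π_i x_{t−i} + ε_t,    π_i ∈ {−1, +1},  π_1 = +1.

The motivation is data that is nonlinear, nonperiodic and nonstationary —
the canonical example is single-channel seizure EEG — where a globally
fitted AR model with free coefficients goes stale as the dynamics drift.
Coercing the weights to ±1 turns estimation into a discrete choice: at
every forecast origin t the 2^(p−1) admissible sign vectors are scored by
least squares on the W most recent one-step pairs (targets x_s, regressors
x_{s−1} … x_{s−p}, s = t−W … t−1).  For each candidate π the intercept has
the closed form ĉ(π) = mean_s(x_s − Σ_i π_i x_{s−i}), so scoring one
candidate is a dot product; the RSS-minimal (π, ĉ) produces the forecast
ĉ + Σ π_i x_{t−i}.  Ties are broken toward the lexicographically smaller
sign vector (+1 before −1, leftmost lag first) so runs are reproducible.
Only p + W trailing samples enter each fit, so the cost per step is
independent of the series length.

The coerced family contains the classical critical cases: all signs +1
with c = 0 is the random walk (unit root at +1), the alternating pattern
is the oscillating unit root at −1.  Every member is nonstationary — the
characteristic roots have product modulus 1 — which is exactly why a
per-origin discrete refit can track data that defeats a stationary fit.

### How the signs are chosen (a design decision)

The coercion idea fixes *what* the coefficients may be, not *how* the ±1
pattern is picked at forecast time.  We operationalize it as the
exhaustive least-squares search above because it is the minimal mechanism
consistent with (a) a per-time-step sign pattern, (b) the first lag pinned
to +1, and (c) fitting by least squares on a handful of trailing points.
The fit window defaults to W = p and is configurable; narrations of this
protocol in the literature are ambiguous about the exact window
accounting, so W is deliberately a free, documented parameter.  The
intercept is re-estimated jointly with the signs at every origin rather
than fixed globally.  An explicit guard refuses p > 20 (≈ 5·10^5
candidates per step) unless forced.

## Order selection by box-counting dimension

The order p is chosen from the geometry of the signal rather than from an
information criterion.  Each reference ("normal") signal is delay-embedded
as V_t = [x_t, x_{t−τ}, …, x_{t−Lτ}] (defaults τ = 1, L = 20), the
box-counting dimension of the resulting point cloud is estimated, the
per-signal slopes are averaged, and p = ⌈mean slope⌉ (an integer mean
stays as it is; the result is at least 1).  Which signals count as the
normal reference collection is the caller's responsibility.

Box counting covers the object with a grid of cells of side ε and fits
the slope d of log N_ε against log(1/ε), since N_ε ≈ k·(1/ε)^d.  The
default ladder doubles ε from 0.1 for 17 steps (0.1 … 6553.6, every size
≤ 10000).  Two counting modes exist:

* **curve** — the planar graph {(t, x_t)} with t in raw 1-based
  sample-index units, counted by *segment–cell intersection* of the
  linear interpolant (a signal trace is a curve, not a scatter).  For a
  function graph the occupied cells in each ε-column form one contiguous
  run of rows, so the implementation refines the polyline at column
  boundaries and sums per-column row spans — O(n + span/ε) per size, and
  exactly equal to enumerating every cell in the bounding box and
  clipping each segment against it (the test suite checks this equality
  against a brute-force Liang–Barsky enumeration on small instances).
  Cells are treated as closed; boundary points belong to both adjacent
  columns.  Expected slope for a planar curve is 1–2; values outside
  provoke a warning, not an error.
* **points** — a phase-space cloud, counted by half-open cell occupancy
  (each vector lands in exactly one hypercube, via per-axis flooring from
  the per-axis minima).  Slopes here legitimately exceed 2 and grow with
  embedding dimension.

Axis units are raw (sample index vs. signal amplitude): an absolute ε
ladder is only meaningful against raw units.  A `normalize` option
rescales the curve into a 4096×4096 box for unit-free use.

**Linear-range policy.**  Log-log box-count plots flatten when ε is far
below the sample spacing or far above the object extent.  The default
`auto` policy fits every contiguous window of ≥ 5 ladder points, skips
windows with zero or constant counts (they carry no scaling information),
and keeps the window with maximal R², breaking ties toward longer windows
and then toward smaller ε.  `full` and explicit index windows are also
available.  R² comparisons are rounded to 12 digits so fp noise cannot
flip a tie.

Calibration on closed-form fixtures (checked by the test suite and the
acceptance script): a straight line and a smooth sine come out near
slope 1; the Weierstrass graph W(t) = Σ a^k cos(b^k π t) with a = 0.7,
b = 3 (theoretical graph dimension 2 + ln a/ln b ≈ 1.675) is recovered
within ±0.2 at 4096 samples — the residual bias is the familiar
finite-sampling effect of box counting, not an implementation artifact;
an i.i.d.-uniform cloud embedded in the plane comes out at slope 2.

## Diagnostics

**Real cepstrum.**  Inverse DFT of the log magnitude spectrum of the
mean-removed signal; spectral magnitudes below 1e−12 of the maximum are
floored before the log.  A component of period q produces a harmonic comb
whose spacing appears as cepstral peaks at quefrency q and its multiples.
Peaks are searched in a band (default 2 … n/2) and ranked by prominence,
ties broken toward descending value and then smaller quefrency — an
ideally periodic signal has *equal* rahmonic peaks at every multiple of
its period, and the fundamental is the smallest of them; the ranking
rounds to 10 relative digits so fp noise cannot break such an exact tie.
A peak is significant when its value exceeds the band median plus 5
normal-consistent MADs.  The scaled MAD matters: the band holds ~n/2
roughly independent values, whose expected maximum under noise is about
√(2 ln(n/2)) ≈ 3.9 robust SDs at n = 4096, so a 5-SD fence keeps the
false-positive rate on white noise in the low percent (the suite checks
≤ 5 in 100 draws) while an impulse-train peak exceeds it by an order of
magnitude.  No taper is applied by default (an option exists): peak
*positions*, not leakage-free amplitudes, are what is read off.

**Lag plots and the randomness verdict.**  `lag_pairs` returns the
(x_{t−L}, x_t) scatter together with the biased (divide-by-n) lag-L
autocorrelation of the mean-centered series, which is bounded by 1.
Reading such plots by eye is the traditional procedure; the package
formalizes it: a series is called random iff |r_L| < 2/√n at every
requested lag.  This is an operationalization, not a literal transcription
of the visual judgement.

## Synthetic data

Generators are pure functions of their arguments including the seed
(numpy `default_rng`), so every stochastic result in the tests and the
acceptance script is re-runnable bit-for-bit on one platform.

* `gen_ar` — stationary AR(p), started at the process mean with a 500
  sample burn-in; nonstationary coefficient vectors are rejected with the
  offending root modulus (the check can be disabled, which is how the
  unit-root identity with the random-walk generator is exercised).
* `gen_sine`, `gen_random_walk` — periodicity and unit-root fixtures.
* `gen_weierstrass` — deterministic fractal fixture with a closed-form
  graph dimension; chosen over fractional Brownian motion because it
  needs no stochastic simulator of its own.  Truncation defaults to
  a^k < 1e−6.
* `simulate_rc_process` — the random-coefficient autoregression
  x_t = Σ φ_ti x_{t−i} + ε_t with each φ_ti drawn i.i.d. as +θ with
  probability α, −θ otherwise.  Unrolling the recursion expresses x_t as
  past noise terms with accumulated ± weights, i.e. a generalized random
  walk whose jumps go up or down with the realized signs; θ = 0
  degenerates to white noise.  The realized coefficient matrix and noise
  vector are returned so tests can verify the recursion identity and the
  two-point moments (E φ = θ(2α−1)) directly.
* `gen_sign_coerced_ar` — forward simulation of the coerced model itself
  with a *fixed* sign pattern.  Since all such patterns are
  nonstationary, only patterns whose characteristic roots lie on the unit
  circle can be simulated over hundreds of steps without overflow; at
  order 3 with π_1 = +1 these are (+1, +1, −1) (roots 1, 1, −1) and
  (+1, −1, +1) (roots 1, ±i).

What the generators do *not* emulate: spike-wave morphology, 1/f spectra,
measurement artifacts, or any other physiological structure of real EEG.
Passing tests therefore demonstrate the estimators' correctness and the
claimed model-class properties, not clinical performance on recordings.

## The head-to-head study

The central comparative claim — that per-origin sign coercion beats a
conventionally refit AR on data from the coerced model class — is tested
on 50 seeded replicates of the order-3 coerced recursion with sign
pattern (+1, +1, −1), intercept 0, noise sd 0.1, length 600, forecasting
samples 501–600 one step ahead (rolling), coerced forecaster at p = 3,
W = 3 against an AR(3) refit by Yule–Walker at every origin on all
history to date.  The coerced forecaster must win on at least 40 of 50.

The sign pattern is the study's one free design choice and was fixed on
these grounds: (+1, +1, −1) is the unique order-3 pattern with π_1 = +1
whose characteristic roots are *all* at the critical unit values ±1 —
it is the order-3 generalization of the random walk and its alternating
counterpart, and produces the drifting, nonstationary trajectories the
coerced model exists for.  The other simulable pattern, (+1, −1, +1),
has complex unit roots (1, ±i) and yields bounded oscillations that look
stationary at the evaluation horizon; on such data a stationary AR fit is
already near-optimal and the two methods are statistically tied, so it
carries no information about the coercion mechanism.  The Yule–Walker
baseline (rather than conditional least squares) is the conventional
"standard AR" estimator; its stationarity assumption is precisely what
the comparison probes, and a least-squares refit — super-consistent on
unit-root data — would instead measure the intercept-noise overhead of
the short coerced window.  Both baselines are available in the
evaluation API (`ModelSpec(method=...)`).

Typical outcome at these settings: coerced median RMSE ≈ 0.12 (close to
the noise floor 0.1 plus the ĉ estimation overhead of a 3-pair window)
against a Yule–Walker median RMSE of roughly 1–4, and 50/50 wins.

## Evaluation harness

Rolling one-step protocol throughout: each forecast uses observed values
through the preceding sample, refitting as the origin advances; accuracy
is RMSE over the horizon.  A `recursive` mode feeds forecasts back once
observed data is exhausted (predictions are then reported without RMSE
unless the whole horizon is observed).  The nearest-neighbor baseline
predicts the successor of the historical window (length m, default = p)
closest in Euclidean distance to the trailing window, earliest match
winning ties; its training span grows by one sample per step, unlike the
coerced forecaster's fixed short window.  Wall-clock timings are
hardware-dependent and are never asserted by tests.

## Numerical and degenerate-input choices

* All user-facing sample indices are 1-based and inclusive; internal
  storage is 0-based numpy.
* The segment loader parses everything as float64, tolerates CRLF and
  surrounding whitespace, skips `#` comment lines (the CLI writes
  reproducibility headers in that form), and rejects NaN/Inf tokens with
  the offending line number.
* Constant series are rejected where the operation is undefined on them
  (AR fitting, cepstrum); the coerced forecaster handles them exactly
  (the intercept absorbs the sign sum).
* Yule–Walker uses biased (divide-by-n) sample autocovariances via
  statsmodels; the intercept is set so the implied process mean equals
  the sample mean.  Conditional least squares uses the min-norm
  solution, so exactly collinear designs (e.g. a noiseless ramp) still
  yield residual-minimizing predictions.
* Problem sizes in the test suite and acceptance script (series of
  600–5000 samples, 20–100 replicates, 4096-sample dimension fixtures)
  were chosen so each study estimates its quantity stably while the whole
  suite stays interactive to run.

## Known limitations

* The exhaustive sign search is exponential in p; p ≤ 10 is comfortable,
  p > 20 is refused without an explicit override.
* Box-counting dimension estimates at 4096 samples carry the usual
  finite-size bias (the Weierstrass fixture reads ≈ 0.14 low); the
  estimator is calibrated, not bias-corrected.
* The cepstrum periodicity verdict depends on a threshold convention
  (median + 5 scaled MADs); a lone sinusoid without harmonics produces a
  cosine-shaped cepstrum whose ripple does not clear the fence — by
  design, the detector responds to harmonic structure.
* Single-channel only; no clinical EEG container formats, no seizure
  alarm logic, no significance testing of RMSE differences.
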