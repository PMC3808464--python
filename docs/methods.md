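# Methods

## The AR-BEKK model

The package models a k-dimensional series as an autoregression whose
innovation covariance is itself driven by the lagged process:

```
x_t = Σ_{i=1..p} A_i x_{t-i} + H_t^{1/2} ε_t,   ε_t ~ iid N(0, I_k)
H_t = W + Σ_{j=1..q} B_j x_{t-j} x_{t-j}' B_j'
```

This is the BEKK volatility form with the lagged *process* in place of the
lagged residual, which couples the second-order statistics to the first-order
ones: the conditional noise variance is a quadratic function of the signal.
`H_t` is positive definite by construction whenever `W` is.  With `B_j = 0`
the model is an ordinary Gaussian VAR, which the package treats as the `q = 0`
special case throughout (simulation, likelihood, fitting, testing), so the
homoskedastic limit is available exactly rather than approximately.

Assumptions: Gaussian innovations; trials are independent realizations of a
common process on a uniform grid; within the joint two-block model the two
blocks' innovation processes are independent, so the joint conditional
covariance is blockdiag(Hx, Hy) and a directed influence lives only in the
mean matrices and in the volatility rows of the *target* block.

### Stability

Two conditions are enforced and exposed:

- first-order: the spectral radius of the VAR companion matrix of
  `A_1..A_p` is below one (any p);
- second-order (p = q = 1 only): the second-moment recursion
  `vec(S) ← M vec(S) + vec(W)` is contractive.  For the single-block model
  `M = A⊗A + B⊗B`; for the joint model the volatility term is projected onto
  the block-diagonal entries of `vec(S)` (stacking `B = [Bx; By]`), which is
  the exact recursion under block-diagonal `H`.  `stationary_second_moment`
  solves the fixed point `vec(S) = (I − M)^{-1} vec(W)`.

Simulation refuses unstable models unless overridden, starts from a zero
state (configurable `initial_state` for stimulus-locked designs), and
discards 500 burn-in samples by default.  The matrix square root used to
color the innovations is the Cholesky factor; for Gaussian innovations any
factor with `L L' = H` gives the same law.

## Likelihood and fitting

The exact conditional log-likelihood conditions on the first
`m = max(p, q)` points of each trial and scores the rest:

```
l_t = −½ [ k ln 2π + ln det H_t + r_t' H_t^{-1} r_t ],
r_t = x_t − Σ_i A_i x_{t-i}
```

summed over trials (trials are independent).  The same conditioning window is
used in full and restricted fits so nested likelihoods are comparable.  For
univariate blocks — the configuration used in all the studies — the
likelihood and its analytic gradient are evaluated in closed vectorized form;
multivariate blocks fall back to batched Cholesky factorizations.

Initialization is two-stage least squares: per-equation OLS for the mean
matrices; then, per channel, the squared AR residuals are regressed on the
squared lagged values with an intercept — the intercept (floored at 1e−6)
starts the baseline variance, the square roots of the non-negative slopes
start the diagonal volatility coefficients (off-diagonal entries start at
zero).  The start is shrunk into the stable region if needed.

Fitting maximizes the likelihood subject to both spectral radii ≤ 1 − ε
(ε = 1e−6), with `W` parameterized through its Cholesky factor so positive
definiteness is free.  Two constrained optimizers are wired in, both with
defaults of 500 iterations and 1e−8 tolerance: a sequential-quadratic
(active-set-style) method as primary and a trust-region interior-point-style
method as fallback.  The SQP method is primary because, on this likelihood,
it reliably converges in tens of iterations where the interior-point method
often exhausts its evaluation budget without improving the optimum.  The full
joint fit is additionally warm-started from the restricted optimum (and the
returned fit is never worse than any start), which enforces the nested-model
inequality `lnL_full ≥ lnL_restricted` up to optimizer tolerance.  A fit that
improves on no start is returned with `converged=False` and the optimizer
trace — never silently.

Free-parameter counts for a univariate pair at p = q = 1: 10 (full) vs 8
(restricted), so the likelihood-ratio statistic has 2 degrees of freedom; in
general df = (p + q)·kx·ky, the number of zeroed coefficients.  This choice
is validated empirically by the null calibration (below).

## Causal tests

- `classical_gc`: nested pooled-least-squares VARs; Geweke's measure
  `F = ln det Σ_r − ln det Σ_f` and the equivalent likelihood-ratio statistic
  `G = n F ~ χ²_{p·kx·ky}`.
- `sdn_gc`: `G = 2(lnL_full − lnL_restricted)` from the joint AR-BEKK fits,
  `χ²` with `(p+q)·kx·ky` df.  With `q = 0` it reproduces the classical
  statistic to optimizer tolerance.
- `difference_test`: under the null the two directed statistics of a pair
  are independent χ² with equal df, so their difference follows the
  symmetric variance-gamma law with density
  `f(d) ∝ |d|^{(df−1)/2} K_{(df−1)/2}(|d|/2)`; the CDF is evaluated by
  adaptive quadrature of this density (CDF(0) = ½ exactly by symmetry).
  df is exposed and defaults to the pair's test df — under df = 2 the
  two-sided tail at 4.61 is ≈ 0.0997, i.e. the distribution is Laplace with
  scale 2; no fixed quantile table is hard-coded.
- `pair_table`: every ordered pair of regions, Bonferroni threshold
  `α / (number of directed tests actually run)`, plus the signed
  difference-of-causalities matrix.  One unrestricted joint fit per
  unordered pair serves both directions.  Non-convergent pairs are flagged
  in the report, never dropped.

## Signal/noise diagnostics

The empirical "signal" of a channel is its least-squares projection onto
basis functions of its own lags, pooled over trials (one coefficient vector
per channel); the "noise" is the residual, and the noise variance at each
within-trial time point is the residual variance across trials.  Basis
families: `linear` (lags), `poly2` (lags and squares), `fourier6`
(sine/cosine pairs of order 1–6 of each lagged value rescaled to [−1, 1] by
the panel range) — 1, 2 and 12 regressors per lag; recommended lag maxima
for sweeps are 9, 6 and 2 respectively.  Collinear design columns are
dropped via pivoted QR and recorded.  A `condition_on` window lets nested
lag counts be compared on identical rows, making R² monotone in the sweep.

`sdn_correlation` is the Pearson (optionally Spearman) correlation, across
within-trial time points (channels pooled by default), between the
trial-mean squared signal and the noise variance; a significant positive
value is the signature of signal-dependent noise.  `model_concordance`
correlates the empirical signal with the fitted model's one-step mean and
the empirical noise variance with the trial-averaged model conditional
variance.  Note a structural limitation: for a *stationary zero-mean* panel
the across-trial variance estimator's own sampling noise bounds the variance
concordance well below one regardless of trial count; the concordance check
is therefore run on trial-locked panels (all trials released from a common
state), where a systematic within-trial variance profile exists — this is
also the regime real task recordings live in.

## BOLD simulator

Poisson spike counts (bin width 1 ms; Fano factor 1) drive the standard
hemodynamic state equations

```
ds/dt = efficacy·u − s/τ_s − (f−1)/τ_f        df/dt = s
dv/dt = (f − v^{1/α})/τ_0                     dq/dt = (f·E(f,E0)/E0 − v^{1/α}q/v)/τ_0
E(f, E0) = 1 − (1−E0)^{1/f}
BOLD = V0·(k1(1−q) + k2(1−q/v) + k3(1−v)) + e_t
```

from rest (0, 1, 1, 1), integrated by explicit Euler at the 1 ms input
resolution (a 4th-order step is available; halving the Euler step changes
the trace by < 0.1%).  Defaults: τ_s = 0.8 s, τ_f = 0.4 s, τ_0 = 1.0 s,
α = 0.32, E0 = 0.34, V0 = 0.02, and 1.5-T observation constants k1 = 7E0,
k2 = 2, k3 = 2E0 − 0.2; observation noise defaults to zero so that all
across-trial variability is of neuronal origin.

The drive `u` is the binned spike count treated as piecewise-constant input
with efficacy 0.5, i.e. one spike injects `0.5·dt` into the vasodilatory
signal.  This keeps the flow/volume states in their physical domain across
the 5–80 Hz range; per-spike injections large enough to produce
percent-scale BOLD deflections drive the flow variable negative and are
rejected by the integrator.  The resulting peak mean responses are ≈ 0.003%,
0.02% and 0.04% at 5, 40 and 80 Hz — small in amplitude, but all the
qualitative properties of interest (monotone peak ordering in rate, peak
across-trial variance above baseline variance, positive and significant
variance-vs-squared-signal correlation) are scale-invariant.  The default
trial is 25 s at 1 ms resolution with a 1-s stimulus window, decimated to
1 Hz (every 1000th sample → 25 samples/trial), 100 trials.

## Preprocessing

Per trial and channel: multilevel db2 wavelet decomposition (symmetric
extension, depth `floor(log2 N) − 1` capped at the wavelet's maximum), soft
thresholding of all detail levels at the universal threshold
`λ = σ̂ √(2 ln N)` with `σ̂ = median(|d1|)/0.6745` estimated once from the
first-level details (hard thresholding by flag); then removal of the
least-squares line and the mean.  Exact numerical agreement with any
particular proprietary wavelet routine is not claimed.  `pool_trials`
concatenates subjects' trials, keeping per-trial subject provenance, under
the repeated-realization assumption.

## Simulation studies and their conditions

**ROC study.**  Random univariate-pair AR-BEKK models: each direction
carries a link independently with probability 0.4; a link sets the
volatility cross-coefficient to 1 (shrunk by 0.9 steps only until the
ensemble member is second-order stable) and, outside variance-only mode, a
mean cross-coefficient ~ U(0.1, 0.5).  Diagonal mean and volatility
coefficients ~ U(0.3, 0.7), baseline variance 1, rejection-sampled to
stability.  Each model yields 2 replicate trials of 1000 points; both tests
are run in both directions and scored against the ground-truth labels by
ROC/AUC.  The reference ensemble is 100 models; the validation suite runs a
30-model ensemble (same conditions) and asserts AUC(sdn) − AUC(classical) >
0.1 in variance-only mode.

**Null calibration.**  400 replicates of two independent AR-BEKK series
(a = b = 0.5, w = 1), 2 trials × 500 points each — a replicate count fixed
by the study design, with the series length chosen as a realistic panel
size comparable to the ROC study's.  The rejection rate at α = 0.05 must
fall in the binomial 95% interval and the p-values must pass a KS
uniformity check at distance < 0.1; this validates the df choice.

**Synthetic four-region study.**  A 4-node AR-BEKK network (diagonal mean
0.45, diagonal volatility 0.35, baseline variance 1) over regions named
OFC, AntINS, AntLPFC, PostLPFC; planted links (mean 0.5, volatility 0.4)
differ by condition — PostLPFC→AntINS under attention to intensity;
AntLPFC→OFC, PostLPFC→OFC and AntINS→OFC under attention to pleasantness.
Dimensions mimic the study design: 12 subjects × 9 trials, 16 samples at a
2-s repetition time, 108 pooled trials per condition.  The planted pattern
is a ground truth for end-to-end recovery (≥ 80% directed-edge accuracy
over 10 seeds; null networks respect the Bonferroni family-wise rate); it
is not a reproduction of any empirical connectivity values.

## What the generators do and do not emulate

The synthetic panels reproduce the dimensions, trial structure and
noise mechanism of repeated-trial BOLD recordings, but not scanner drift,
physiological confounds, inter-subject heterogeneity (all subjects share
one generating model), hemodynamic lag differences between regions, or
spatial preprocessing artifacts.  Passing the validation suite shows the
estimator and tests are correct and well calibrated *under the model class
and these idealized conditions*; it does not certify performance on real
data where those unmodeled features matter.

## Numerical choices and limitations

- Constrained fits support p = q = 1 (plus q = 0); the mean-order companion
  stability check supports any p.  Likelihood evaluation supports general
  (p, q).
- Stability margin ε = 1e−6; initialization floors variance intercepts at
  1e−6; degenerate (constant) panels are rejected.
- Only |B| entries are identified in univariate models (±b give identical
  laws); recovery is assessed on magnitudes.
- The LR statistic is reported unclamped (tiny negatives possible at
  optimizer tolerance); p-values use max(G, 0).
- The difference-of-causalities test assumes independence of the two
  directed statistics, an approximation when both derive from the same pair.
- CSV round-trips are lossless (17-significant-digit formatting,
  round-trip float parsing).
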