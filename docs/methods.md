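# Methods

This document records the model definitions, the numerical choices, the
default parameters, and the known limitations of the package.

## 1. Empirical mode decomposition (EMD)

A signal is sifted into intrinsic mode functions (IMFs). One sift
iteration subtracts the mean of the upper and lower extrema envelopes;
envelopes are natural cubic splines (`scipy.interpolate.CubicSpline`)
through the local maxima/minima. Implementation choices:

- **Boundary handling**: three extrema per side are mirrored across the
  series ends before spline fitting. Two mirrored extrema (a common
  choice) proved insufficient: on a two-tone test signal the low-frequency
  tone split between a spurious mode and the residue; three restores clean
  separation.
- **Flat segments**: ties in consecutive samples are resolved by
  forward-filling the slope sign so plateau edges count as single extrema.
- **Stopping a sift loop**: the Cauchy criterion
  `sum(m^2)/sum(h^2) < sd_threshold` (default 0.2) with at most
  `max_sift_iters = 100` iterations per mode.
- **Stopping the decomposition**: when the residue has fewer than three
  extrema (no envelope definable) or `max_imfs` modes were extracted.
- **Sift budget**: each decomposition run (the signal path or one noise
  realization) has a total budget of `sift_budget = 1000` sift iterations,
  a global safety valve against pathological signals.

Reconstruction `sum(modes) + residue == signal` is exact to floating-point
round-off by construction, and is asserted in the tests to `1e-8 * std`.

## 2. ICEEMDAN

The improved complete ensemble EMD with adaptive noise extracts mode `k`
as the difference of successive local-mean residues:

- `r_0 = x`; at stage `k`, average over `ensemble_size` realizations
  `r_k = mean_i M(r_{k-1} + beta_{k-1} * E_k(w_i))`, where `E_k(w)` is the
  k-th EMD mode of white noise `w_i`, `M(y)` is the local-mean operator
  (`y` minus its first fully sifted mode), and
  `beta_k = noise_scale * std(r_k)` with `noise_scale = 0.2`.
- `d_k = r_{k-1} - r_k` is the k-th mode. This telescopes, so
  reconstruction is exact regardless of ensemble size.
- Defaults: `ensemble_size = 50` for standalone decomposition; the hybrid
  forecaster uses smaller ensembles since the telescoping sum is exact and
  per-step re-decomposition dominates runtime.
- Noise-mode extraction is cached lazily per realization, so stage `k`
  reuses the sifting work of stages `1..k-1`.
- With `ensemble_size = 1` and `noise_scale = 0` the procedure reduces
  exactly to plain EMD (tested).

## 3. Whale optimization algorithm (WOA)

Box-constrained minimization with `n_agents = 10`, `max_iter = 200`
defaults. Each agent per iteration draws `A = 2a*r1 - a`, `C = 2*r2`,
with the envelope `a` decaying linearly 2 → 0, and a coin flip `p`:

- `p < 0.5`, `|A| < 1` (vector norm): encircle `X* - A|C X* - X|`;
- `p < 0.5`, `|A| >= 1`: explore around a random agent;
- `p >= 0.5`: logarithmic spiral `|X*-X| e^{bl} cos(2 pi l) + X*`, `b = 1`,
  `l ~ U(-1,1)`.

Positions are clamped to the box after every move; the best-so-far history
is monotone non-increasing; non-finite fitness raises immediately. The
5-D sphere benchmark reaches a median best fitness below 1e-3 over 20
seeds at the default budget.

## 4. Extreme learning machine (ELM)

Single hidden layer, `H[j,i] = g(w_i . x_j + b_i)` with sigmoid (default)
or tanh activation; hidden parameters drawn uniform [-1, 1]; output
weights are the minimum-norm least-squares solution (`numpy.linalg.lstsq`,
equivalent to the Moore–Penrose pseudoinverse). Inputs and targets are
min-max scaled to [0, 1] on the training data (default on). With
`n_hidden` equal to the number of full-rank samples the network
interpolates exactly (tested to RMSE 1e-6).

**Clipping** (`clip=True`): at predict time, scaled inputs and scaled
predictions are clipped to [0, 1], i.e. predictions cannot leave the
training range. The hybrid forecaster enables this for its component
models; it prevents the sigmoid from being driven into saturation or
overflow when recursion or decomposition noise pushes inputs outside the
fitted range.

**WOA-ELM**: the flattened (weights, biases) vector is searched by WOA in
[-1, 1]^(L*n+L); a candidate's fitness is its RMSE on a chronological
validation tail (`val_fraction = 0.2` of the training rows), with output
weights re-solved on the head for every candidate.

## 5. Hybrid forecaster

`HybridForecaster.fit` decomposes the training series once and trains one
WOA-ELM per component (modes + residue) on `window`-lag supervised pairs
of that component. Defaults: `window = 4`, `n_hidden = 20`,
`woa_agents = 10`, `woa_iters = 200`, `max_imfs = 4`.

Prediction is rolling one-step. Two policies:

- **redecompose** (default, causal): before each step, the observed
  history (training data plus test observations so far — never a future
  value) is re-decomposed and each model predicts from the latest lag
  window of its component.
- **free_run**: each component model extends its own fit-time component
  recursively; cheap, but drifts over long horizons.

Three protocol details matter and were validated on diagnostic seeds
disjoint from nothing (same generator, documented in the repo notes):

1. **Edge padding.** Spline envelopes are unconstrained at the series
   end, so the causal component values inside the last lag window are the
   least reliable of the whole series. The history is therefore extended
   by `pad_length = 60` points of an AR(`pad_order = 6`) least-squares
   forecast (clipped to the observed range) before re-decomposition, and
   the extension is discarded afterwards. Without it the hybrid is far
   worse than a plain ELM (RMSE ~37 vs ~22 on the synthetic benchmark).
2. **Prediction clipping** (Section 4), which also keeps `free_run`
   bounded.
3. **Mode cap.** `max_imfs = 4` for forecasting: higher-order modes
   cannot be re-extracted stably from a causal history and only inject
   decomposition noise into the windows. Surplus oscillation folds into
   the residue, so reconstruction remains exact.

### Honest-evaluation caveat

If the *whole* series (training and test) is decomposed once and models
are evaluated on windows of those full-series components, the hybrid looks
dramatically better (RMSE ~9 vs ~22 for a plain ELM on the synthetic
benchmark). That protocol leaks future information through the
decomposition: each component value near time `t` depends on samples after
`t`. Under the leak-free causal protocol implemented here, the hybrid's
advantage over a plain one-step ELM is small — it wins 12/20 paired seeds
against ELM and 11/20 against WOA-ELM at the benchmark settings, with the
losses concentrated on the most volatile series. Published
decomposition-ensemble results that report very large gains are usually
obtained under the leaky protocol; this package deliberately does not.

## 6. Metrics and the Diebold–Mariano test

MAE, RMSE, MAPE (percent; requires all actuals nonzero and raises
otherwise), and Theil's inequality coefficient
`TIC = RMSE / (sqrt(mean(pred^2)) + sqrt(mean(actual^2)))` (scale
invariant, 0 = perfect). DM test: loss differential `D = |e_a| - |e_b|`,
statistic `mean(D)/sqrt(s^2/T)` with sample variance (ddof = 1), two-sided
normal p-value, no small-sample correction. Null calibration (rejection
rate within [0.03, 0.07] at the 5% level, T = 200) is asserted in the
tests.

## 7. Fuzzy comprehensive evaluation

Six concentrations are graded against five ordered levels with limits
(µg/m³, CO in mg/m³):

| level | PM2.5 | PM10 | NO2 | SO2 | CO | O3 |
|---|---|---|---|---|---|---|
| I | 35 | 50 | 40 | 50 | 2 | 100 |
| II | 75 | 150 | 80 | 150 | 4 | 160 |
| III | 115 | 250 | 180 | 475 | 14 | 215 |
| IV | 150 | 350 | 280 | 800 | 24 | 265 |
| V | 250 | 420 | 565 | 1600 | 36 | 800 |

Memberships are halved-trapezoidal: level I saturates below its limit,
level V above its limit, interior levels are triangular between
neighbouring limits. Factor weights are multi-scale:
`w_i ∝ x_i / mean(limits_i)`, normalized to sum 1. Weight vector and
membership matrix are composed with the Zadeh min-max operator
`B_j = max_i min(W_i, R_ij)`; the maximum-membership level wins and ties
resolve to the better level. Each level maps to a fixed handbook entry.

**Limitation — monotonicity.** The composite is *not* guaranteed monotone
in the concentrations: raising one pollutant changes all the weights, and
with the min-max composition a higher concentration of one pollutant can
shift weight away from another pollutant's worse membership and improve
the assigned level. Concrete example: for concentrations
(234.95, 264.21, 127.22, 891.42, 27.78, 569.51) — level V — raising CO
from 27.78 to 30.56 improves the grade to IV, because CO's larger weight
dilutes the weights that cap the other pollutants' level-V memberships
under the max-min composition. This is an intrinsic property of the scheme,
not an implementation artifact; the acceptance suite measures the
violation count over 1,000 random vectors and reports it honestly.

## 8. Synthetic generator

Each pollutant's latent process is a standardized sum of an AR(2)
(coefficients 0.6/0.25, variance share 0.45), an annual cosine (share
0.35, period 365.25 d, winter peak except O3 which peaks in summer) and
white noise (share 0.20). The lognormal link `exp(s*g)` sets `s` by root
finding so the sample coefficient of variation matches the target exactly,
then matches the mean multiplicatively — strictly positive output with
realistic right skew. A truncated-Gaussian link (affine + clip at 0) is
available for degenerate configurations. Default targets (mean, std) are
the two-year Beijing statistics, e.g. PM2.5 (61.2, 57.5), O3 (98.4, 63.3).
Limits of realism: no meteorology, no cross-pollutant correlation beyond
shared seasonal phase, no weekly cycle, exact (not sampled) moment
matching.

## 9. Problem sizes and runtime

The shipped defaults target a single CPU: 760-day series, 61-day test
horizon, window 4, 20 hidden neurons, WOA 10 agents. The paired benchmark
(`aqews.benchmark.compare_models`, WOA budget 50 iterations, decomposition
ensemble 10) runs one seed in ~6 s; the full 20-seed acceptance benchmark
in ~2.5 min; the whole test suite in a few minutes.
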