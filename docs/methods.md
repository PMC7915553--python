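# Methods

## Model and assumptions

Each spatial axis of a tracked particle is modelled independently by the
scalar linear-Gaussian system

```
x[k+1] = a x[k] + b + w[k],   w[k] ~ N(0, q),   q = 2 D Δt
y[k]   = x[k] + v[k],         v[k] ~ N(0, r),
```

sampled uniformly at interval Δt (s), positions in μm. The parameters
θ = (a, b, q, r) are assumed piecewise constant: fixed for a finite
stretch of steps, then switching discretely to new values an unknown
number of times. The framework covers pure diffusion (a = 1, b = 0),
Ornstein–Uhlenbeck/confined motion (a < 1), and directed transport
(b ≠ 0), but not anomalous (non-Markovian, non-Gaussian) dynamics, motion
blur, or missing frames — the constant-time-step assumption is enforced
at the CSV reader.

`q` and `D` are kept mutually consistent through `q = 2DΔt` at every
conversion point. Both `q` and `r` are floored at 1e−12 μm² inside all
recursions: the benchmark's stationary regime has D = 0 exactly, which
the likelihood machinery cannot represent (it assumes some process
stochasticity), and the floor keeps every recursion defined. The
practical consequence, visible in the benchmark results, is that the
transition coefficient of a truly stationary segment is biased low —
estimator compensation for forbidden zero process noise.

## Stage 1 — local-likelihood EM

The local likelihood at center t weights each sample's conditional
log-likelihood by a kernel K((k − t)/h) from the polynomial family
(1 − v²)^γ normalized to unit integral on [−1, 1] (γ = 0 uniform,
1 Epanechnikov, 2 biweight). **Window convention:** h is the
*half*-width; the support centered at t spans up to 2h + 1 samples. This
is the literal reading of K((k − t)/h) and matters when comparing window
sizes across implementations. Near the trajectory ends the window is
truncated and all normalizations use the realized weight sums (no
padding or reflection).

EM alternates:

- **E-step** — Kalman filter + Rauch–Tung–Striebel smoother run over the
  kernel support only, with a diffuse prior (mean = first window
  observation, variance 1e4 μm²) at the window's left edge. The smoother
  supplies means, variances and lag-one cross-covariances
  (Cov(x[k+1], x[k] | Y) = J[k] P[k+1|N]), verified against brute-force
  joint-Gaussian conditioning to 1e−8 in the tests.
- **M-step** — closed-form weighted updates: (â, b̂) solve the 2×2
  normal equations of the augmented regressor [x; 1]; q̂ and r̂ are
  weighted mean squared (smoothed) residuals. The transition sums have
  one fewer term than the observation sums, so q̂ divides by the weight
  sum over transitions and r̂ by the weight sum over observations; with
  a uniform kernel over the whole series this makes the fixed point the
  exact (conditional-free) MLE, which the tests confirm against direct
  1-D likelihood maximization to 1e−4.

Any subset of {a, b, q, r} can be pinned to known values (e.g. estimate
only D with a, b, r known). Initialization is method-of-moments from
first differences (var(Δy) ≈ q + 2r for a random walk, split 2:1);
convergence is declared when the max relative change of free parameters
drops below 1e−6 (default) or after 200 iterations. The auxiliary
function is checked to be non-decreasing within every iteration — the EM
ascent guarantee — and, for uniform kernels (exact EM), the innovation
log-likelihood itself is monotone.

The stage-1 scan slides the center with a configurable stride
(default 10) and warm-starts each center from the previous estimate; a
"fixed" init policy makes the scan stride-independent for comparisons.
Its output is advisory only — it suggests how many switches the data
contains and thereby the detection threshold; it contributes no final
numbers.

## Stage 2 — AR/CUSUM change detection

The observation series is described by an AR(p) model with intercept
(the intercept absorbs the drift of directed motion; it can be disabled).
The order is selected by BIC(p) = −2 l(θ̂) + p log N over p = 1..p_max,
with every candidate fit on the same conditional sample (the first p_max
observations held back); without the common sample the shrinking term
count tilts selection toward higher orders.

Detection compares a long-term model M0 (all data since the last reset)
with a short-term model M1 (trailing window of h_cd samples) through the
CUSUM statistic

```
s[k] = ½ log(σ₀²/σ₁²) + e₀[k]²/(2σ₀²) − e₁[k]²/(2σ₁²)
g[k] = max(g[k−1] + s[k], 0),    declare change when g[k] ≥ λ.
```

Numerical choices that matter:

- **Predictive residuals.** Both models are fit on data through k − 1
  and predict y[k]; σ² estimates are degree-of-freedom corrected. With
  in-sample residuals and ML variances the increment has a *positive*
  mean under the null (≈ +0.02/step at h_cd = 100), which guarantees
  false alarms; the predictive form has the small negative null drift a
  CUSUM needs (≈ −0.013/step).
- **Warm-up.** No increment is accumulated until M0 has
  max(2p + 2, 20) samples and M1's window fits inside the current epoch.
- **Change-time assignment.** The reported time is the start of M1's
  window at detection, floored by the onset of the detector's final
  positive excursion (the last step with g = 0 — the classical CUSUM
  maximum-likelihood change-point estimate). The window-start rule alone
  anticipates the change by up to h_cd when the crossing is fast (an
  abrupt drift onset crosses λ = 2.1 within a few steps); the excursion
  floor removes that overshoot while reducing to the window-start rule
  for slow, spectral changes.
- **Reset.** After a detection both models reset and the epoch restarts
  at the *detection* step, discarding everything earlier; restarting at
  the estimated change time would leave pre-change samples in M0 and
  produce echo detections.

Offline two-pass use: the detector runs on the series and on its
reversal (backward times mapped as N + 1 − t). A forward/backward pair
is matched when each lies within match_tol of their average
(|f − b| ≤ 2·match_tol), nearest pairs first; matched pairs are averaged
(the passes bracket the true change from opposite sides, so averaging
cancels most of the delay bias), unmatched forward detections are kept,
and backward-only detections are dropped. Detections closer than
min_separation are merged keeping the earlier one. Multi-axis input sums
the per-axis increments before accumulation (independent axes ⇒
log-likelihood ratios add); a per-axis mode (union of detections) is
available.

Defaults: p = 1, λ = 2.1, h_cd = 200, match_tol = min_separation = h_cd.
h_cd is the one free scale of the detector; 200 samples stabilizes the
short-window variance enough that λ ≈ 2 thresholds give a clean null on
benchmark-scale data, and it equals the default stage-1 window so both
stages resolve changes at the same time scale. λ remains a user choice,
to be set with the stage-1 scan in hand.

## Stage 3 — segment EM

Detected change times tile the trajectory into maximal segments (a
change time is the first step of the new regime). Each segment of at
least 18 samples (2 × 4 parameters + 10; shorter segments are reported
unestimated) is fit by the same EM machinery, windowed to the segment
with an Epanechnikov kernel by default: detection is inexact, so samples
at the segment edges may belong to the neighboring regime and are
downweighted (the kernel half-width extends one step past the segment so
true edge samples keep small positive weight). A uniform kernel
reproduces the plain EM estimate. When ground truth is supplied,
segments are matched to true regimes by maximal overlap and percent
errors 100·|θ̂ − θ|/|θ| are attached; where the truth is exactly zero
the relative error is undefined and the absolute error is reported with
a flag instead.

## Simulator

`simulate_trajectory` draws exact Gaussian sample paths of the model,
with the segment active at step k governing the k → k+1 transition, and
returns both the latent and observed series; identical seeds give
bit-identical output. The benchmark schedule (`four_regime_model`) is
1000 steps at Δt = 0.1 s in four 250-step regimes — free diffusion
(D = 0.1 μm²/s), Ornstein–Uhlenbeck (a = 0.86, D = 0.01), stationary
(D = 0), directed (b = −0.1 μm/step ≙ 2 μm/s, D = 0.01) — with
localization-noise variance r = 0.0045 μm² (precision ≈ 67 nm) matching
the imaging conditions of the laboratory validation this schedule
emulates. What the simulator deliberately omits relative to real
microscopy data: camera-integration motion blur, localization errors
correlated with the motion or varying with signal intensity, missed/false
localizations, and any coupling between axes. Passing tests therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to these experimental artifacts.

## Problem sizes used in tests and the acceptance script

Chosen to exercise each claim at meaningful statistical power while
keeping a default run comfortably fast: 20–50 seeds for Monte-Carlo
properties, N = 5000 for slow-converging pure-diffusion recovery
(q/r ≈ 10 makes r weakly identified), N = 8000 as the largest point of
the bias-shrinkage check, and 30 pipeline runs in the acceptance script.

## Known limitations

- AR-order selection on full benchmark-length (N = 1000) diffusion+noise
  trajectories genuinely prefers p = 2: such data is ARIMA(0,1,1), whose
  AR(2) approximation reduces the residual variance by more than the BIC
  penalty at that length. Short runs (N ≈ 100–200) select p = 1. The
  detector's default stays p = 1, which is entirely adequate for
  detection.
- Stationary (D = 0) regimes violate the stochasticity assumption; their
  a-estimates are biased low (see above).
- Detecting a variance decrease is intrinsically slower than an
  increase; the two-pass average mitigates but does not remove the
  asymmetry.
- No streaming/online guarantees: the detector is designed for offline,
  full-trajectory analysis.
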