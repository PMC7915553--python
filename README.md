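# trackem

Estimation of **time-varying motion-model parameters** from single
particle tracking (SPT) trajectories.

Fluorescently labelled biomolecules tracked inside living cells rarely
keep one mode of motion: a protein may diffuse freely, become tethered,
pause, and then be carried by a motor. `trackem` analyzes a localized
position time series and returns *when* the motion model switched and the
maximum-likelihood parameters of each constant-parameter stretch.

## Model

Each spatial axis is treated independently as a scalar linear-Gaussian
state-space system with piecewise-constant parameters,

```
x[k+1] = a x[k] + b + w[k],   w[k] ~ N(0, q),   q = 2 D Δt
y[k]   = x[k] + v[k],         v[k] ~ N(0, r)
```

with `x` the true position (μm), `y` the localization, `D` the diffusion
coefficient (μm²/s), `b` a per-step drift (μm), and `r` the
localization-noise variance (μm², i.e. `sqrt(r)` is the localization
precision). `a = 1, b = 0` is pure diffusion; `a < 1` an
Ornstein–Uhlenbeck (tethered/confined) process; `b ≠ 0` directed
transport.

The analysis has three stages:

1. **Sliding-window EM** — kernel-weighted ("local") likelihood,
   maximized by EM with a Kalman-smoother E-step, gives a parameter
   estimate at every time point. These curves are advisory: they indicate
   how many switches the data contains.
2. **Change detection** — the series is described by a low-order AR model
   (order chosen by BIC); a two-model CUSUM compares a long-term fit
   against a sliding-window fit and declares a change when the
   accumulated log-likelihood ratio crosses a threshold λ. Because SPT
   analysis is offline, the detector runs forward *and* backward in time
   and matched detections are averaged, cancelling most detection-delay
   bias.
3. **Segment EM** — EM is rerun on each detected segment (with an
   Epanechnikov kernel that downweights possibly misassigned edge
   samples) to produce the final estimates.

A simulator for piecewise-constant-parameter trajectories is included, so
the whole pipeline is testable end-to-end without external data; its
built-in benchmark schedule (diffusion → Ornstein–Uhlenbeck → stationary
→ directed, 250 steps each) mirrors a laboratory validation experiment in
which a piezostage physically replays numerically generated sample paths
under a real microscope.

## Worked example

```python
from trackem import PipelineConfig, four_regime_model, run_pipeline, simulate_trajectory

model = four_regime_model(r=0.0045, dt=0.1, n_steps=1000)
traj = simulate_trajectory(model, seed=12)

cfg = PipelineConfig()
cfg.stage1.enabled = False   # advisory stage; see examples/02
cfg.cd.p = 1
cfg.cd.lam = 2.1

res = run_pipeline(traj, cfg, truth=model)
```

prints (via `examples/04_full_pipeline.py`):

```
detected change times: [254, 534, 803] (true: 251, 501, 751)
segment        a_hat    b_hat     D_hat     r_hat
   1- 253    0.9213   0.0266    0.1133   0.00248
 254- 533    0.8160  -0.0012    0.0091   0.00468
 534- 802    1.0349  -0.0050    0.0097   0.00388
 803-1000    1.0000  -0.0975    0.0105   0.00543
```

The three switches are found within a few tens of steps of the truth, and
each segment's fit recovers its regime: free diffusion with `D ≈ 0.11`
(truth 0.1 μm²/s), mean reversion `a ≈ 0.82` (truth 0.86), and directed
transport with `b ≈ -0.098` μm/step (truth −0.1, i.e. 2 μm/s at
Δt = 0.1 s). `sqrt(r_hat) ≈ 0.05–0.07` μm is the implied localization
precision. The one caveat is the stationary third regime: with `D = 0`
the model's assumption of process stochasticity is violated and `a_hat`
there is unreliable — the same bias the laboratory validation reports.

The `examples/` directory has one short script per capability
(simulation, stage-1 scan, change detection, full pipeline), and the same
functionality is exposed as a thin CLI:

```sh
trackem simulate --out traj.csv --seed 1
trackem run --traj traj.csv --out results/ --skip-stage1
```

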