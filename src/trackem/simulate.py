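"""Simulation of piecewise-constant linear-Gaussian SPT trajectories.

The simulator draws latent positions from x[k+1] = a*x[k] + b + w[k] and
observations y[k] = x[k] + v[k], with the parameters of the segment active
at step k governing the transition k -> k+1.  It is the test bed for the
whole pipeline: the benchmark four-regime schedule (free diffusion ->
Ornstein-Uhlenbeck -> stationary -> directed transport) mirrors controlled
laboratory "synthetic motion" experiments where a piezostage replays a
numerically generated sample path under a real microscope.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .model import MotionParameters, PiecewiseModel, Trajectory

__all__ = ["simulate_trajectory", "four_regime_model"]


def simulate_trajectory(
    model: PiecewiseModel,
    seed: Optional[int] = None,
    x1: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    axis_label: str = "x",
) -> Trajectory:
    """Draw one trajectory (latent x and observed y) from ``model``.

    ``x1`` is the initial latent position (um); the same seed reproduces
    the same trajectory bit-for-bit.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = model.n_steps
    a, b, q, r = model.per_step_arrays()

    w = rng.standard_normal(n - 1) * np.sqrt(q[: n - 1])
    v = rng.standard_normal(n) * np.sqrt(r)

    x = np.empty(n)
    x[0] = x1
    xa, xb = a.tolist(), b.tolist()
    xw = w.tolist()
    cur = float(x1)
    for k in range(n - 1):
        cur = xa[k] * cur + xb[k] + xw[k]
        x[k + 1] = cur
    y = x + v
    return Trajectory(y=y, dt=model.dt, x=x, axis_label=axis_label)


def four_regime_model(
    r: float = 0.0045,
    dt: float = 0.1,
    n_steps: int = 1000,
) -> PiecewiseModel:
    """Benchmark schedule: four 250-step regimes over 1000 steps.

    Regime 1 (steps 1-250): pure diffusion, D = 0.1 um^2/s.
    Regime 2 (251-500):     Ornstein-Uhlenbeck, a = 0.86, D = 0.01.
    Regime 3 (501-750):     stationary particle, D = 0.
    Regime 4 (751-1000):    directed motion, b = -0.1 um/step (2 um/s at
                            dt = 0.1 s, dynein-like speed), D = 0.01.

    ``r`` defaults to 0.0045 um^2 (localization precision ~67 nm),
    matching the imaging conditions of the laboratory validation data this
    schedule reproduces.
    """
    if n_steps < 4:
        raise ValueError("n_steps must be >= 4")
    quarters = [1 + i * (n_steps // 4) for i in range(4)]
    pars = [
        MotionParameters(a=1.0, b=0.0, D=0.1, r=r),
        MotionParameters(a=0.86, b=0.0, D=0.01, r=r),
        MotionParameters(a=1.0, b=0.0, D=0.0, r=r),
        MotionParameters(a=1.0, b=-0.1, D=0.01, r=r),
    ]
    return PiecewiseModel(list(zip(quarters, pars)), n_steps=n_steps, dt=dt)
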