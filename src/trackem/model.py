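"""Linear-Gaussian motion model for single particle tracking.

One spatial axis is modelled by the scalar state-space system

    x[k+1] = a * x[k] + b + w[k],   w[k] ~ N(0, q),   q = 2 * D * dt
    y[k]   = x[k] + v[k],           v[k] ~ N(0, r)

where ``x`` is the true particle position (um), ``y`` the localized
position, ``D`` the diffusion coefficient (um^2/s), ``b`` a per-step drift
(um) and ``r`` the localization-noise variance (um^2).  ``a = 1, b = 0``
gives pure diffusion; ``a < 1`` an Ornstein-Uhlenbeck (tethered/confined)
process; ``b != 0`` directed transport.  Parameters may be piecewise
constant in time (:class:`PiecewiseModel`).

This module provides the parameter containers, the exact scalar Kalman
filter and Rauch-Tung-Striebel smoother (with lag-one cross-covariances,
which the EM updates need), and conversions between ``D`` and the per-step
process-noise variance ``q``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VARIANCE_FLOOR",
    "MotionParameters",
    "PiecewiseModel",
    "Trajectory",
    "FilterState",
    "SmoothedState",
    "diffusion_to_process_variance",
    "process_variance_to_diffusion",
    "kalman_filter",
    "kalman_smoother",
]

#: Variance floor (um^2) applied to q and r inside all recursions.  The
#: stationary regime of the benchmark schedule has D = 0 exactly, which the
#: EM machinery cannot represent (it assumes some process stochasticity);
#: the floor keeps every recursion defined.
VARIANCE_FLOOR = 1e-12

#: Default diffuse prior variance (um^2) on the initial state.
DIFFUSE_PRIOR_VAR = 1e4


def diffusion_to_process_variance(D: float, dt: float) -> float:
    """Per-step process-noise variance q = 2*D*dt (um^2)."""
    if D < 0:
        raise ValueError(f"diffusion coefficient must be >= 0, got {D}")
    if dt <= 0:
        raise ValueError(f"sampling interval must be > 0, got {dt}")
    return 2.0 * D * dt


def process_variance_to_diffusion(q: float, dt: float) -> float:
    """Inverse of :func:`diffusion_to_process_variance`: D = q / (2*dt)."""
    if q < 0:
        raise ValueError(f"process variance must be >= 0, got {q}")
    if dt <= 0:
        raise ValueError(f"sampling interval must be > 0, got {dt}")
    return q / (2.0 * dt)


@dataclass(frozen=True)
class MotionParameters:
    """One regime of the motion model.

    Parameters
    ----------
    a : float
        State-transition coefficient (unitless).  1 for free/directed
        diffusion, < 1 for Ornstein-Uhlenbeck dynamics.
    b : float
        Drift per step (um).
    D : float
        Diffusion coefficient (um^2/s).
    r : float
        Localization (measurement) noise variance (um^2).
    """

    a: float
    b: float
    D: float
    r: float

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")
        if self.r < 0:
            raise ValueError(f"r must be >= 0, got {self.r}")

    def q(self, dt: float) -> float:
        """Process-noise variance for sampling interval ``dt`` (um^2)."""
        return diffusion_to_process_variance(self.D, dt)

    @classmethod
    def from_q(cls, a: float, b: float, q: float, r: float, dt: float) -> "MotionParameters":
        """Build from the per-step process variance instead of D."""
        return cls(a=a, b=b, D=process_variance_to_diffusion(q, dt), r=r)

    def localization_precision(self) -> float:
        """Localization precision sqrt(r) in um (std dev of position error)."""
        return math.sqrt(self.r)


@dataclass(frozen=True)
class PiecewiseModel:
    """Piecewise-constant parameter schedule over steps 1..n_steps.

    ``segments`` is an ordered list of ``(start_index, MotionParameters)``
    with 1-based inclusive start indices; the first must start at 1 and the
    indices must be strictly increasing.  The parameters of the segment
    active at step k govern the transition from k to k+1.
    """

    segments: tuple
    n_steps: int
    dt: float

    def __init__(self, segments: Sequence, n_steps: int, dt: float):
        segments = tuple((int(s), p) for s, p in segments)
        if not segments:
            raise ValueError("need at least one segment")
        if segments[0][0] != 1:
            raise ValueError("first segment must start at step 1")
        starts = [s for s, _ in segments]
        if any(s2 <= s1 for s1, s2 in zip(starts, starts[1:])):
            raise ValueError("segment start indices must be strictly increasing")
        if starts[-1] > n_steps:
            raise ValueError("segment starts beyond trajectory length")
        if dt <= 0:
            raise ValueError("dt must be > 0")
        object.__setattr__(self, "segments", segments)
        object.__setattr__(self, "n_steps", int(n_steps))
        object.__setattr__(self, "dt", float(dt))

    def segment_bounds(self) -> list:
        """1-based inclusive (start, end) per segment."""
        starts = [s for s, _ in self.segments]
        ends = [s - 1 for s in starts[1:]] + [self.n_steps]
        return list(zip(starts, ends))

    def params_at(self, k: int) -> MotionParameters:
        """Parameters active at step k (1-based)."""
        if not 1 <= k <= self.n_steps:
            raise ValueError(f"step {k} outside 1..{self.n_steps}")
        out = self.segments[0][1]
        for s, p in self.segments:
            if s <= k:
                out = p
            else:
                break
        return out

    def segment_index(self) -> np.ndarray:
        """0-based segment label per step, length n_steps."""
        lab = np.zeros(self.n_steps, dtype=int)
        for i, (s, _) in enumerate(self.segments):
            lab[s - 1:] = i
        return lab

    def per_step_arrays(self):
        """(a, b, q, r) arrays of length n_steps, q = 2*D*dt."""
        lab = self.segment_index()
        pars = [p for _, p in self.segments]
        a = np.array([pars[i].a for i in lab])
        b = np.array([pars[i].b for i in lab])
        q = np.array([pars[i].q(self.dt) for i in lab])
        r = np.array([pars[i].r for i in lab])
        return a, b, q, r


@dataclass
class Trajectory:
    """Observed 1-D position series with uniform sampling interval.

    ``y`` holds the localized positions (um), ``x`` optionally the true
    latent positions when the trajectory was simulated.
    """

    y: np.ndarray
    dt: float
    x: Optional[np.ndarray] = None
    axis_label: str = "x"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1 or self.y.size < 2:
            raise ValueError("y must be a 1-D series of length >= 2")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.x is not None:
            self.x = np.asarray(self.x, dtype=float)
            if self.x.shape != self.y.shape:
                raise ValueError("x and y must have the same length")

    def __len__(self) -> int:
        return self.y.size


@dataclass
class FilterState:
    """Kalman-filter output: one-step predictions, filtered moments,
    innovations, and the exact Gaussian log-likelihood of the data."""

    pred_mean: np.ndarray   # x_hat[k|k-1]
    pred_var: np.ndarray    # P[k|k-1]
    filt_mean: np.ndarray   # x_hat[k|k]
    filt_var: np.ndarray    # P[k|k]
    innovations: np.ndarray     # e[k] = y[k] - x_hat[k|k-1]
    innovation_var: np.ndarray  # S[k]
    loglik: float
    gains: np.ndarray       # Kalman gains, kept for the smoother


@dataclass
class SmoothedState:
    """Smoother output: posterior moments given the whole series.

    ``lag_one[k]`` is Cov(x[k+1], x[k] | all data), length N-1; the EM
    cross-moment sums need it.
    """

    mean: np.ndarray      # x_hat[k|N]
    var: np.ndarray       # P[k|N]
    lag_one: np.ndarray   # P[k+1,k|N]


def kalman_filter(
    traj: Trajectory,
    params: MotionParameters,
    prior_mean: Optional[float] = None,
    prior_var: float = DIFFUSE_PRIOR_VAR,
) -> FilterState:
    """Forward Kalman recursion for constant parameters.

    The prior is placed on x[1] directly (default: mean = y[1], diffuse
    variance), so the innovation log-likelihood equals the exact joint
    Gaussian log-density of the observations under model + prior.
    """
    if prior_var <= 0:
        raise ValueError("prior variance must be > 0")
    y = traj.y
    n = y.size
    a, b = params.a, params.b
    q = max(params.q(traj.dt), VARIANCE_FLOOR)
    r = max(params.r, VARIANCE_FLOOR)
    m0 = float(y[0]) if prior_mean is None else float(prior_mean)

    pm = np.empty(n)
    pv = np.empty(n)
    fm = np.empty(n)
    fv = np.empty(n)
    e = np.empty(n)
    S = np.empty(n)
    K = np.empty(n)

    mp, Pp = m0, float(prior_var)
    ll = 0.0
    log2pi = math.log(2.0 * math.pi)
    yy = y.tolist()
    for k in range(n):
        pm[k] = mp
        pv[k] = Pp
        Sk = Pp + r
        ek = yy[k] - mp
        Kk = Pp / Sk
        mf = mp + Kk * ek
        Pf = Pp - Kk * Pp
        fm[k] = mf
        fv[k] = Pf
        e[k] = ek
        S[k] = Sk
        K[k] = Kk
        ll -= 0.5 * (log2pi + math.log(Sk) + ek * ek / Sk)
        mp = a * mf + b
        Pp = a * a * Pf + q

    return FilterState(pm, pv, fm, fv, e, S, ll, K)


def kalman_smoother(filt: FilterState, params: MotionParameters) -> SmoothedState:
    """Rauch-Tung-Striebel backward pass with lag-one cross-covariances.

    Uses the RTS identity Cov(x[k+1], x[k] | Y) = J[k] * P[k+1|N] with
    smoother gain J[k] = P[k|k] * a / P[k+1|k].
    """
    a = params.a
    fm, fv = filt.filt_mean, filt.filt_var
    pm, pv = filt.pred_mean, filt.pred_var
    n = fm.size

    sm = np.empty(n)
    sv = np.empty(n)
    lag = np.empty(max(n - 1, 0))

    sm[n - 1] = fm[n - 1]
    sv[n - 1] = fv[n - 1]
    for k in range(n - 2, -1, -1):
        J = fv[k] * a / pv[k + 1]
        sm[k] = fm[k] + J * (sm[k + 1] - pm[k + 1])
        sv[k] = fv[k] + J * J * (sv[k + 1] - pv[k + 1])
        lag[k] = J * sv[k + 1]
    return SmoothedState(sm, sv, lag)
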