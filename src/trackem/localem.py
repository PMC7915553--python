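"""Kernel-weighted (local likelihood) EM for the linear-Gaussian SPT model.

Estimation is done inside a window centered at a time index t.  Each sample
k receives weight K((k - t)/h) from a polynomial kernel family

    K(v) = (1 - v^2)^gamma / (2^(2*gamma+1) * B(gamma+1, gamma+1)),  |v| <= 1

(gamma = 0: uniform, 1: Epanechnikov, 2: biweight).  The E-step runs the
Kalman smoother over the window with the current parameters; the M-step
solves the weighted complete-data normal equations in closed form.  Sliding
the window along the trajectory yields a time-varying parameter estimate;
running a single window over a detected segment (with an Epanechnikov
kernel to downweight possibly mislabelled edge samples) yields the final
per-segment maximum-likelihood estimate.

Any subset of {a, b, q, r} can be pinned to known values, e.g. to estimate
only the diffusion coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import betaln

from .model import (
    VARIANCE_FLOOR,
    DIFFUSE_PRIOR_VAR,
    MotionParameters,
    SmoothedState,
    Trajectory,
    kalman_filter,
    kalman_smoother,
)

__all__ = [
    "KernelSpec",
    "SufficientStats",
    "LocalEstimate",
    "SegmentEstimate",
    "kernel_weight",
    "window_weights",
    "sufficient_stats",
    "em_update",
    "local_em_estimate",
    "sliding_window_scan",
    "segment_em",
    "local_loglik",
    "default_init",
    "MIN_SEGMENT_LENGTH",
]

#: Minimum number of samples accepted by :func:`segment_em`
#: (2 x 4 model parameters + 10).
MIN_SEGMENT_LENGTH = 18


@dataclass(frozen=True)
class KernelSpec:
    """Kernel shape ``gamma`` and window half-width ``h`` (samples).

    The support of the window centered at t is |k - t| <= h, i.e. up to
    2h + 1 samples.
    """

    gamma: int = 1
    h: int = 200

    def __post_init__(self) -> None:
        if self.gamma < 0 or int(self.gamma) != self.gamma:
            raise ValueError("gamma must be a nonnegative integer")
        if self.h < 1:
            raise ValueError("window half-width h must be >= 1")


def kernel_weight(v, gamma: int):
    """Kernel value K(v); vectorized over v, zero outside |v| <= 1."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    v = np.asarray(v, dtype=float)
    norm = math.exp(-(2 * gamma + 1) * math.log(2.0) - betaln(gamma + 1, gamma + 1))
    inside = np.abs(v) <= 1.0
    out = np.where(inside, (1.0 - np.minimum(v * v, 1.0)) ** gamma * norm, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def window_weights(t: float, kernel: KernelSpec, n: int) -> Tuple[int, int, np.ndarray]:
    """Weights for a window centered at (possibly fractional) index t.

    Returns 1-based inclusive bounds (lo, hi) of the in-support samples,
    truncated at the trajectory ends, and the weight array for k in
    lo..hi.  No reflection or padding near the boundaries.
    """
    lo = max(1, int(math.ceil(t - kernel.h)))
    hi = min(n, int(math.floor(t + kernel.h)))
    if lo > hi:
        raise ValueError(f"window centered at {t} does not overlap trajectory")
    k = np.arange(lo, hi + 1, dtype=float)
    w = kernel_weight((k - t) / kernel.h, kernel.gamma)
    if not np.any(w > 0):
        raise ValueError(f"window centered at {t} has zero total weight")
    return lo, hi, w


@dataclass
class SufficientStats:
    """Weighted complete-data moments from one E-step.

    ``S00`` is the 2x2 moment matrix of the augmented regressor [x; 1],
    ``S01`` the cross-moment row [sum w*(x[k+1]x[k] + P[k+1,k]), sum
    w*x[k+1]], ``S11`` the next-state second moment, and ``Sr`` the
    weighted observation residual sum(w * ((y - x_hat)^2 + P)).  ``n_q``
    and ``n_r`` are the effective sample sizes of the transition and
    observation sums.
    """

    S00: np.ndarray
    S01: np.ndarray
    S11: float
    Sr: float
    n_q: float
    n_r: float


def sufficient_stats(smoothed: SmoothedState, y: np.ndarray, weights: np.ndarray) -> SufficientStats:
    """Accumulate the weighted EM moments over one window.

    ``smoothed`` and ``y`` must be aligned with ``weights`` (same window).
    Transition sums run over k = lo..hi-1 weighted by the kernel value at
    k; observation sums over k = lo..hi.
    """
    w = np.asarray(weights, dtype=float)
    m, P, lag = smoothed.mean, smoothed.var, smoothed.lag_one
    if not (len(w) == len(y) == len(m)):
        raise ValueError("weights, data and smoothed moments must be aligned")
    n_r = float(np.sum(w))
    if n_r <= 0:
        raise ValueError("empty effective window (all weights zero)")
    wt = w[:-1]
    n_q = float(np.sum(wt))
    S00 = np.array(
        [
            [float(np.sum(wt * (m[:-1] ** 2 + P[:-1]))), float(np.sum(wt * m[:-1]))],
            [float(np.sum(wt * m[:-1])), n_q],
        ]
    )
    S01 = np.array(
        [float(np.sum(wt * (m[1:] * m[:-1] + lag))), float(np.sum(wt * m[1:]))]
    )
    S11 = float(np.sum(wt * (m[1:] ** 2 + P[1:])))
    Sr = float(np.sum(w * ((y - m) ** 2 + P)))
    return SufficientStats(S00=S00, S01=S01, S11=S11, Sr=Sr, n_q=n_q, n_r=n_r)


def _aux_value(a: float, b: float, q: float, r: float, st: SufficientStats) -> float:
    """Expected complete-data log-likelihood (constants dropped)."""
    xi = np.array([a, b])
    quad = st.S11 - 2.0 * float(xi @ st.S01) + float(xi @ st.S00 @ xi)
    return -0.5 * (
        st.n_q * math.log(q) + quad / q + st.n_r * math.log(r) + st.Sr / r
    )


def em_update(
    stats: SufficientStats,
    current: Tuple[float, float, float, float],
    pinned: Optional[Dict[str, float]] = None,
    floor: float = VARIANCE_FLOOR,
) -> Tuple[Tuple[float, float, float, float], float, float]:
    """One M-step: maximize the auxiliary function given the E-step moments.

    ``current`` is (a, b, q, r); entries named in ``pinned`` are held at
    their pinned values.  Returns the updated parameters and the auxiliary
    value before/after the update (after >= before up to round-off).

    Free (a, b) solve the 2x2 weighted normal equations Xi = S01 S00^-1;
    q and r are weighted mean squared residuals, floored at ``floor``.
    A singular S00 falls back to a ridge-regularized solve.
    """
    pinned = pinned or {}
    a0, b0, q0, r0 = current
    aux_before = _aux_value(
        pinned.get("a", a0), pinned.get("b", b0),
        max(pinned.get("q", q0), floor), max(pinned.get("r", r0), floor), stats)

    S00, S01 = stats.S00, stats.S01
    a_free, b_free = "a" not in pinned, "b" not in pinned
    if a_free and b_free:
        try:
            xi = np.linalg.solve(S00, S01)
        except np.linalg.LinAlgError:
            import warnings

            warnings.warn("singular S00; using ridge-regularized solve")
            xi = np.linalg.solve(S00 + 1e-10 * np.eye(2) * max(np.trace(S00), 1.0), S01)
        a_new, b_new = float(xi[0]), float(xi[1])
    elif a_free:
        b_new = pinned["b"]
        a_new = (S01[0] - b_new * S00[0, 1]) / max(S00[0, 0], floor)
    elif b_free:
        a_new = pinned["a"]
        b_new = (S01[1] - a_new * S00[0, 1]) / max(S00[1, 1], floor)
    else:
        a_new, b_new = pinned["a"], pinned["b"]

    if "q" in pinned:
        q_new = max(pinned["q"], floor)
    else:
        xi = np.array([a_new, b_new])
        quad = stats.S11 - 2.0 * float(xi @ stats.S01) + float(xi @ stats.S00 @ xi)
        q_new = max(quad / stats.n_q, floor)
    if "r" in pinned:
        r_new = max(pinned["r"], floor)
    else:
        r_new = max(stats.Sr / stats.n_r, floor)

    aux_after = _aux_value(a_new, b_new, q_new, r_new, stats)
    return (a_new, b_new, q_new, r_new), aux_before, aux_after


@dataclass
class LocalEstimate:
    """EM estimate at one window center.

    ``aux_gains`` holds (before, after) auxiliary values per iteration;
    ``after >= before`` within each iteration is the EM ascent guarantee.
    ``logliks`` is the kernel-weighted innovation log-likelihood at each
    iterate.
    """

    t: float
    params: MotionParameters
    q: float
    iterations: int
    converged: bool
    aux_gains: List[Tuple[float, float]] = field(default_factory=list)
    logliks: List[float] = field(default_factory=list)


@dataclass
class SegmentEstimate:
    """Final per-segment estimate (1-based inclusive [start, end]).

    ``params`` is None for segments too short to estimate (reported but
    skipped).  ``percent_errors`` maps parameter name to (error, relative)
    where ``relative`` is False when the truth is zero and the error is
    absolute instead.
    """

    start: int
    end: int
    params: Optional[MotionParameters]
    q: Optional[float]
    iterations: int
    converged: bool
    axis_label: str = "x"
    percent_errors: Optional[Dict[str, Tuple[float, bool]]] = None


def default_init(traj: Trajectory, lo: int = 1, hi: Optional[int] = None) -> Tuple[float, float, float, float]:
    """Method-of-moments starting point (a, b, q, r) from first differences.

    var(diff y) = q + 2r for a random walk; split it 2:1 between q and r.
    """
    hi = len(traj) if hi is None else hi
    d = np.diff(traj.y[lo - 1:hi])
    v = float(np.var(d)) if d.size > 1 else 1e-4
    v = max(v, 10 * VARIANCE_FLOOR)
    return 1.0, 0.0, 0.5 * v, 0.25 * v


def local_loglik(
    traj: Trajectory,
    t: float,
    kernel: KernelSpec,
    params: MotionParameters,
    prior_var: float = DIFFUSE_PRIOR_VAR,
) -> float:
    """Kernel-weighted innovation log-likelihood sum_k K[k,t] l(y[k] | theta)."""
    lo, hi, w = window_weights(t, kernel, len(traj))
    sub = Trajectory(y=traj.y[lo - 1:hi], dt=traj.dt)
    filt = kalman_filter(sub, params, prior_mean=float(sub.y[0]), prior_var=prior_var)
    per_step = -0.5 * (
        math.log(2.0 * math.pi)
        + np.log(filt.innovation_var)
        + filt.innovations ** 2 / filt.innovation_var
    )
    return float(np.sum(w * per_step))


def local_em_estimate(
    traj: Trajectory,
    t: float,
    kernel: KernelSpec,
    init: Optional[Tuple[float, float, float, float]] = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    pinned: Optional[Dict[str, float]] = None,
    prior_var: float = DIFFUSE_PRIOR_VAR,
    track_loglik: bool = False,
) -> LocalEstimate:
    """EM at one window center.

    Alternates the smoother E-step (over the kernel support only, diffuse
    prior at the window's left edge) with the closed-form M-step until the
    max relative change of the free parameters drops below ``tol`` or
    ``max_iter`` is reached.  ``pinned`` fixes any of {a, b, q, r}.
    """
    pinned = dict(pinned or {})
    n = len(traj)
    lo, hi, w = window_weights(t, kernel, n)
    sub = Trajectory(y=traj.y[lo - 1:hi], dt=traj.dt)

    if init is None:
        cur = default_init(traj, lo, hi)
    else:
        cur = tuple(float(v) for v in init)
    cur = (
        pinned.get("a", cur[0]),
        pinned.get("b", cur[1]),
        max(pinned.get("q", cur[2]), VARIANCE_FLOOR),
        max(pinned.get("r", cur[3]), VARIANCE_FLOOR),
    )

    free = [nm for nm in ("a", "b", "q", "r") if nm not in pinned]
    gains: List[Tuple[float, float]] = []
    lls: List[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p_cur = MotionParameters.from_q(cur[0], cur[1], cur[2], cur[3], traj.dt)
        filt = kalman_filter(sub, p_cur, prior_mean=float(sub.y[0]), prior_var=prior_var)
        if track_loglik:
            per_step = -0.5 * (
                math.log(2.0 * math.pi)
                + np.log(filt.innovation_var)
                + filt.innovations ** 2 / filt.innovation_var
            )
            lls.append(float(np.sum(w * per_step)))
        smo = kalman_smoother(filt, p_cur)
        stats = sufficient_stats(smo, sub.y, w)
        new, aux_b, aux_a = em_update(stats, cur, pinned)
        gains.append((aux_b, aux_a))

        names = dict(zip(("a", "b", "q", "r"), range(4)))
        rel = 0.0
        for nm in free:
            i = names[nm]
            denom = max(abs(cur[i]), abs(new[i]), 1e-12)
            rel = max(rel, abs(new[i] - cur[i]) / denom)
        cur = new
        if rel < tol:
            converged = True
            break

    return LocalEstimate(
        t=t,
        params=MotionParameters.from_q(cur[0], cur[1], cur[2], cur[3], traj.dt),
        q=cur[2],
        iterations=it,
        converged=converged,
        aux_gains=gains,
        logliks=lls,
    )


def sliding_window_scan(
    traj: Trajectory,
    kernel: KernelSpec,
    stride: int = 1,
    init: Optional[Tuple[float, float, float, float]] = None,
    pinned: Optional[Dict[str, float]] = None,
    init_policy: str = "warm",
    tol: float = 1e-5,
    max_iter: int = 100,
) -> List[LocalEstimate]:
    """Stage-1 scan: one EM estimate per window center t = 1, 1+stride, ...

    ``init_policy`` is "warm" (start each center from the previous
    estimate, the default) or "fixed" (restart from ``init`` / the
    method-of-moments default at every center, making the scan independent
    of the stride).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if init_policy not in ("warm", "fixed"):
        raise ValueError("init_policy must be 'warm' or 'fixed'")
    n = len(traj)
    out: List[LocalEstimate] = []
    carry = init
    for t in range(1, n + 1, stride):
        est = local_em_estimate(
            traj, t, kernel, init=carry, tol=tol, max_iter=max_iter, pinned=pinned
        )
        out.append(est)
        if init_policy == "warm":
            carry = (est.params.a, est.params.b, est.q, est.params.r)
        else:
            carry = init
    return out


def segment_em(
    traj: Trajectory,
    start: int,
    end: int,
    gamma: int = 1,
    init: Optional[Tuple[float, float, float, float]] = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    pinned: Optional[Dict[str, float]] = None,
) -> SegmentEstimate:
    """Stage-3 EM on the samples of one detected segment only.

    The default Epanechnikov kernel (gamma = 1) downweights the segment
    edges, which may belong to a neighboring regime when the detected
    change times are slightly off; ``gamma = 0`` gives the plain
    (unweighted) EM estimate.
    """
    n = len(traj)
    if not (1 <= start < end <= n):
        raise ValueError(f"need 1 <= start < end <= {n}, got [{start}, {end}]")
    length = end - start + 1
    if length < MIN_SEGMENT_LENGTH:
        raise ValueError(
            f"segment [{start}, {end}] has {length} samples; "
            f"minimum is {MIN_SEGMENT_LENGTH}"
        )
    t = 0.5 * (start + end)
    # half-width slightly past the segment ends so edge samples keep a
    # small positive weight under smooth kernels
    h = int(math.ceil((end - start) / 2)) + 1
    kernel = KernelSpec(gamma=gamma, h=h)
    lo = max(1, int(math.ceil(t - h)))
    hi = min(n, int(math.floor(t + h)))
    # restrict to the segment proper: zero out weights outside [start, end]
    seg = Trajectory(y=traj.y[start - 1:end], dt=traj.dt, axis_label=traj.axis_label)
    k = np.arange(start, end + 1, dtype=float)
    est = _segment_local_em(seg, kernel_weight((k - t) / h, gamma), init, tol, max_iter, pinned)
    return SegmentEstimate(
        start=start,
        end=end,
        params=est.params,
        q=est.q,
        iterations=est.iterations,
        converged=est.converged,
    )


def _segment_local_em(seg, weights, init, tol, max_iter, pinned) -> LocalEstimate:
    """EM over an explicit window with explicit weights."""
    pinned = dict(pinned or {})
    if init is None:
        cur = default_init(seg)
    else:
        cur = tuple(float(v) for v in init)
    cur = (
        pinned.get("a", cur[0]),
        pinned.get("b", cur[1]),
        max(pinned.get("q", cur[2]), VARIANCE_FLOOR),
        max(pinned.get("r", cur[3]), VARIANCE_FLOOR),
    )
    free = [nm for nm in ("a", "b", "q", "r") if nm not in pinned]
    names = dict(zip(("a", "b", "q", "r"), range(4)))
    converged = False
    it = 0
    gains: List[Tuple[float, float]] = []
    for it in range(1, max_iter + 1):
        p_cur = MotionParameters.from_q(cur[0], cur[1], cur[2], cur[3], seg.dt)
        filt = kalman_filter(seg, p_cur, prior_mean=float(seg.y[0]))
        smo = kalman_smoother(filt, p_cur)
        stats = sufficient_stats(smo, seg.y, weights)
        new, aux_b, aux_a = em_update(stats, cur, pinned)
        gains.append((aux_b, aux_a))
        rel = 0.0
        for nm in free:
            i = names[nm]
            denom = max(abs(cur[i]), abs(new[i]), 1e-12)
            rel = max(rel, abs(new[i] - cur[i]) / denom)
        cur = new
        if rel < tol:
            converged = True
            break
    return LocalEstimate(
        t=0.0,
        params=MotionParameters.from_q(cur[0], cur[1], cur[2], cur[3], seg.dt),
        q=cur[2],
        iterations=it,
        converged=converged,
        aux_gains=gains,
    )
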