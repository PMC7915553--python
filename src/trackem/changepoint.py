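"""Offline change-point detection for SPT position series (stage 2).

The observations are described by a low-order autoregressive (AR) model

    y[k] = c + sum_i a_i * y[k-i] + eps[k],   var(eps) = sigma^2

whose residual variance captures the spectral changes caused by switches
in diffusion coefficient, confinement or drift.  The AR order is selected
by the Bayesian information criterion BIC(p) = -2 l(theta_hat) + p log N.

Detection runs a two-model CUSUM: a long-term model M0 fit on all data
since the last detected change and a short-term model M1 fit on a trailing
sliding window of ``h_cd`` samples.  The per-step log-likelihood-ratio
increment

    s[k] = 0.5 * log(sigma0^2 / sigma1^2)
           + e0[k]^2 / (2 sigma0^2) - e1[k]^2 / (2 sigma1^2)

is accumulated through the positive-part recursion g[k] = max(g[k-1] +
s[k], 0); a change is declared when g crosses a user threshold ``lam``,
and the change time is the start of M1's window at detection.  After a
detection both models reset and scanning restarts.  Because SPT analysis
is offline, the scan is run forward and backward in time and detections
from the two passes that agree within ``match_tol`` are averaged, which
cancels most of the detection-delay bias.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ARXModel",
    "CusumTrace",
    "ChangePoint",
    "ChangePointSet",
    "fit_ar",
    "ar_loglik",
    "bic_order_select",
    "cusum_scan",
    "Detection",
    "detect_single_pass",
    "detect_two_pass",
    "merge_passes",
]

SIGMA_FLOOR = 1e-12


@dataclass
class ARXModel:
    """Fitted AR model: y[k] = intercept + coef . y[k-1..k-p] + eps."""

    p: int
    coef: np.ndarray
    intercept: float
    sigma2: float
    n_fit: int
    include_intercept: bool = True

    def predict_row(self, lags: np.ndarray) -> float:
        """One-step prediction from the lag vector [y[k-1], ..., y[k-p]]."""
        return float(np.dot(self.coef, lags) + self.intercept)


def _design(y: np.ndarray, p: int, include_intercept: bool) -> Tuple[np.ndarray, np.ndarray]:
    n = y.size
    X = np.empty((n - p, p + (1 if include_intercept else 0)))
    for i in range(p):
        X[:, i] = y[p - 1 - i : n - 1 - i]
    if include_intercept:
        X[:, p] = 1.0
    return X, y[p:]


def fit_ar(y: Sequence[float], p: int, include_intercept: bool = True) -> ARXModel:
    """Conditional least-squares AR(p) fit.

    The drift term of directed motion appears as a constant offset in the
    observations, so an intercept is included by default.  The residual
    variance is the mean squared residual over the n - p usable steps.
    """
    y = np.asarray(y, dtype=float)
    if p < 1:
        raise ValueError("order p must be >= 1")
    if y.size < p + 2:
        raise ValueError(f"need at least {p + 2} samples to fit AR({p})")
    X, t = _design(y, p, include_intercept)
    gram = X.T @ X
    rhs = X.T @ t
    try:
        beta = np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient AR regressors; ridge-regularized solve")
        d = gram.shape[0]
        beta = np.linalg.solve(gram + 1e-10 * max(np.trace(gram), 1.0) * np.eye(d), rhs)
    resid = t - X @ beta
    sigma2 = max(float(np.mean(resid**2)), SIGMA_FLOOR)
    intercept = float(beta[p]) if include_intercept else 0.0
    return ARXModel(
        p=p,
        coef=np.asarray(beta[:p], dtype=float),
        intercept=intercept,
        sigma2=sigma2,
        n_fit=int(y.size),
        include_intercept=include_intercept,
    )


def ar_loglik(model: ARXModel) -> float:
    """Conditional Gaussian log-likelihood at the least-squares fit."""
    m = model.n_fit - model.p
    return -0.5 * m * (math.log(2.0 * math.pi * model.sigma2) + 1.0)


def bic_order_select(
    y: Sequence[float],
    p_max: int = 10,
    include_intercept: bool = True,
) -> Tuple[int, List[Tuple[int, float]]]:
    """Select the AR order minimizing BIC(p) = -2 l(theta_hat) + p log N.

    All candidate orders are fit on the same conditional sample (the
    first ``p_max`` observations serve as initial conditions for every
    p), so their likelihoods are directly comparable — otherwise the
    shrinking sample systematically favors higher orders.  Returns the
    selected order and the full (p, BIC) table.
    """
    y = np.asarray(y, dtype=float)
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    n = y.size
    if n < p_max + 2:
        raise ValueError(f"need at least {p_max + 2} samples for p_max={p_max}")
    table: List[Tuple[int, float]] = []
    for p in range(1, p_max + 1):
        model = fit_ar(y[p_max - p:], p, include_intercept=include_intercept)
        table.append((p, -2.0 * ar_loglik(model) + p * math.log(n)))
    best = min(table, key=lambda t: t[1])[0]
    return best, table


class Detection(NamedTuple):
    """One threshold crossing: estimated change time and detection step."""

    t_change: int
    t_detect: int


@dataclass
class CusumTrace:
    """Per-step detector internals of one scan (1-based time index k)."""

    k: np.ndarray
    s: np.ndarray
    g: np.ndarray
    e0: np.ndarray
    e1: np.ndarray


@dataclass
class ChangePoint:
    """One detected model switch (1-based step of the new regime's start)."""

    t_final: int
    t_forward: Optional[int] = None
    t_backward: Optional[int] = None
    matched: bool = False


@dataclass
class ChangePointSet:
    """Ordered change points with the detector settings that produced them."""

    points: List[ChangePoint]
    lam: float
    h_cd: int
    p: int

    @property
    def times(self) -> List[int]:
        return [cp.t_final for cp in points] if (points := self.points) else []


class _RunningAR:
    """Incremental AR fits on arbitrary index ranges via cumulative sums.

    Rows x[k] = [y[k-1], ..., y[k-p], 1] exist for 0-based k in p..n-1;
    cumulative Gram matrices let any interval [i0, i1] be fit in O(p^2).
    """

    def __init__(self, y: np.ndarray, p: int, include_intercept: bool = True):
        self.y = np.asarray(y, dtype=float)
        self.p = p
        n = self.y.size
        d = p + (1 if include_intercept else 0)
        rows = np.empty((n, d))
        rows[:p] = 0.0
        for i in range(p):
            rows[p:, i] = self.y[p - 1 - i : n - 1 - i]
        if include_intercept:
            rows[p:, p] = 1.0
        self.rows = rows
        outer = rows[:, :, None] * rows[:, None, :]
        tgt = np.zeros(n)
        tgt[p:] = self.y[p:]
        self.cG = np.cumsum(outer, axis=0)
        self.cXy = np.cumsum(rows * tgt[:, None], axis=0)
        self.cyy = np.cumsum(tgt**2)

    def fit(self, i0: int, i1: int) -> Tuple[np.ndarray, float]:
        """LS fit on target indices i0..i1 (0-based, both >= p)."""
        G = self.cG[i1] - (self.cG[i0 - 1] if i0 > 0 else 0.0)
        Xy = self.cXy[i1] - (self.cXy[i0 - 1] if i0 > 0 else 0.0)
        yy = self.cyy[i1] - (self.cyy[i0 - 1] if i0 > 0 else 0.0)
        m = i1 - i0 + 1
        d = G.shape[0]
        try:
            beta = np.linalg.solve(G, Xy)
        except np.linalg.LinAlgError:
            beta = np.linalg.solve(G + 1e-10 * max(np.trace(G), 1.0) * np.eye(d), Xy)
        ssr = yy - 2.0 * float(beta @ Xy) + float(beta @ G @ beta)
        # degree-of-freedom corrected: without it the short-window variance
        # is biased low and the log term of the CUSUM increment acquires a
        # positive drift under the null, causing systematic false alarms
        sigma2 = max(ssr / max(m - d, 1), SIGMA_FLOOR)
        return beta, sigma2

    def residual(self, k: int, beta: np.ndarray) -> float:
        return float(self.y[k] - self.rows[k] @ beta)


def _as_series_list(y) -> List[np.ndarray]:
    if isinstance(y, (list, tuple)) and len(y) and np.ndim(y[0]) == 1:
        series = [np.asarray(a, dtype=float) for a in y]
        if len({a.size for a in series}) != 1:
            raise ValueError("all axes must have the same length")
        return series
    arr = np.asarray(y, dtype=float)
    if arr.ndim == 1:
        return [arr]
    return [arr[i] for i in range(arr.shape[0])]


def cusum_scan(
    y,
    p: int,
    h_cd: int,
    lam: float,
    start: int = 1,
    include_intercept: bool = True,
    collect_trace: bool = False,
    _runners: Optional[List[_RunningAR]] = None,
) -> Tuple[Optional[CusumTrace], Optional["Detection"]]:
    """One CUSUM sweep from 1-based ``start``; stops at the first detection.

    Returns (trace, detection) where ``detection`` holds the estimated
    change time ``t_change`` and the crossing step ``t_detect`` (both
    1-based), or None if g never reaches ``lam``.  Multi-axis input (list of equal-length series)
    sums the per-axis log-likelihood-ratio increments before accumulation.

    Residuals are one-step-ahead: each model is fit on data through k - 1
    and predicts y[k], so the increment s[k] is a genuine out-of-sample
    likelihood ratio (in-sample residuals give the detector a positive
    drift under the null).  No increment is accumulated until the
    long-term model has at least max(2p + 2, 20) samples and the sliding
    window is entirely inside the current epoch.

    The reported change time is the start of the short-term model's window
    at detection, floored by the onset of the detector's final positive
    excursion (the last step at which g was zero): when the threshold is
    crossed faster than one window length — e.g. at an abrupt drift onset
    — the window start predates the change, and the excursion onset is the
    maximum-likelihood change-time estimate of CUSUM theory.
    """
    series = _as_series_list(y)
    n = series[0].size
    if h_cd < p + 2:
        raise ValueError("h_cd must be at least p + 2")
    runners = _runners or [_RunningAR(a, p, include_intercept) for a in series]
    s0 = start - 1  # 0-based epoch start
    warm = max(2 * p + 2, 20)
    first = s0 + p  # first 0-based index with a complete lag vector in epoch

    ks: List[int] = []
    ss: List[float] = []
    gs: List[float] = []
    e0s: List[float] = []
    e1s: List[float] = []
    g = 0.0
    onset = None  # 0-based step after the last g == 0
    for k in range(first, n):
        m0 = k - first  # samples available through k - 1
        w_lo = k - h_cd  # short-term window [k - h_cd, k - 1]
        if m0 < warm or w_lo < first:
            continue
        sk = 0.0
        e0 = e1 = 0.0
        for run in runners:
            beta0, sig0 = run.fit(first, k - 1)
            beta1, sig1 = run.fit(w_lo, k - 1)
            e0 = run.residual(k, beta0)
            e1 = run.residual(k, beta1)
            sk += (
                0.5 * math.log(sig0 / sig1)
                + e0 * e0 / (2.0 * sig0)
                - e1 * e1 / (2.0 * sig1)
            )
        g = max(g + sk, 0.0)
        if g == 0.0:
            onset = None
        elif onset is None:
            onset = k
        if collect_trace:
            ks.append(k + 1)
            ss.append(sk)
            gs.append(g)
            e0s.append(e0)
            e1s.append(e1)
        if g >= lam:
            trace = (
                CusumTrace(np.array(ks), np.array(ss), np.array(gs), np.array(e0s), np.array(e1s))
                if collect_trace
                else None
            )
            tc = w_lo  # 0-based start of M1's window
            if onset is not None and onset > tc:
                tc = onset
            return trace, Detection(t_change=tc + 1, t_detect=k + 1)
    trace = (
        CusumTrace(np.array(ks), np.array(ss), np.array(gs), np.array(e0s), np.array(e1s))
        if collect_trace
        else None
    )
    return trace, None


def detect_single_pass(
    y,
    p: int,
    h_cd: int,
    lam: float,
    include_intercept: bool = True,
    min_separation: Optional[int] = None,
) -> List[int]:
    """Repeated CUSUM sweeps with model resets at each detection.

    After each detection both models reset and the epoch restarts at the
    detection (crossing) step, discarding all prior data; detections
    closer than ``min_separation`` (default ``h_cd``) are merged keeping
    the earlier one.
    """
    series = _as_series_list(y)
    runners = [_RunningAR(a, p, include_intercept) for a in series]
    n = series[0].size
    min_sep = h_cd if min_separation is None else min_separation
    times: List[int] = []
    start = 1
    while True:
        _, det = cusum_scan(
            series, p, h_cd, lam, start=start, include_intercept=include_intercept,
            _runners=runners,
        )
        if det is None:
            break
        tc = max(det.t_change, start + 1)  # progress guard
        times.append(tc)
        # discard all data before the detection step: restarting at the
        # estimated change time would leave pre-change samples in the
        # long-term model and trigger echo detections
        start = det.t_detect
        if start >= n - p - 1:
            break
    merged: List[int] = []
    for t in times:
        if merged and t - merged[-1] < min_sep:
            continue
        merged.append(t)
    return merged


def merge_passes(
    forward: Sequence[int],
    backward: Sequence[int],
    match_tol: int,
) -> List[ChangePoint]:
    """Merge forward- and backward-pass detections (both in forward time).

    A forward/backward pair is "close enough" when each lies within
    ``match_tol`` of their average, i.e. |f - b| <= 2 * match_tol (the
    two passes bracket the true change from opposite sides, so the
    tolerance bounds how far the averaged estimate moves either
    detection).  Eligible pairs are greedily matched nearest-first and
    averaged (rounded); unmatched forward detections are kept as-is;
    backward-only detections are dropped.
    """
    fwd = list(forward)
    bwd = list(backward)
    pairs = sorted(
        ((abs(f - b), i, j) for i, f in enumerate(fwd) for j, b in enumerate(bwd)),
        key=lambda t: t[0],
    )
    used_f: set = set()
    used_b: set = set()
    match: dict = {}
    for d, i, j in pairs:
        if d > 2 * match_tol:
            break
        if i in used_f or j in used_b:
            continue
        used_f.add(i)
        used_b.add(j)
        match[i] = j
    out: List[ChangePoint] = []
    for i, f in enumerate(fwd):
        if i in match:
            b = bwd[match[i]]
            out.append(
                ChangePoint(
                    t_final=int(round((f + b) / 2.0)),
                    t_forward=f,
                    t_backward=b,
                    matched=True,
                )
            )
        else:
            out.append(ChangePoint(t_final=f, t_forward=f, matched=False))
    out.sort(key=lambda cp: cp.t_final)
    return out


def detect_two_pass(
    y,
    p: int,
    h_cd: int,
    lam: float,
    match_tol: Optional[int] = None,
    include_intercept: bool = True,
    min_separation: Optional[int] = None,
) -> ChangePointSet:
    """Two-pass (forward + time-reversed) detection with averaging.

    Backward detections at reversed index t' map to forward time
    N + 1 - t'.  Matched pairs are averaged; forward-only detections are
    kept; backward-only detections are dropped.
    """
    series = _as_series_list(y)
    n = series[0].size
    tol = h_cd if match_tol is None else match_tol
    min_sep = h_cd if min_separation is None else min_separation

    fwd = detect_single_pass(
        series, p, h_cd, lam, include_intercept=include_intercept,
        min_separation=min_sep,
    )
    rev = [a[::-1].copy() for a in series]
    bwd_rev = detect_single_pass(
        rev, p, h_cd, lam, include_intercept=include_intercept,
        min_separation=min_sep,
    )
    bwd = sorted(n + 1 - t for t in bwd_rev)

    points = merge_passes(fwd, bwd, tol)
    pruned: List[ChangePoint] = []
    for cp in points:
        if pruned and cp.t_final - pruned[-1].t_final < min_sep:
            continue
        if not (1 < cp.t_final < n):
            continue
        pruned.append(cp)
    return ChangePointSet(points=pruned, lam=lam, h_cd=h_cd, p=p)
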