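"""Three-stage pipeline: sliding-window scan, change detection, segment EM.

Stage 1 (optional at run time) produces a time-varying parameter estimate
whose only role is to suggest how many model switches the data contains,
guiding the user's choice of the CUSUM threshold.  Stage 2 segments the
trajectory with the two-pass AR/CUSUM detector.  Stage 3 reruns EM on each
maximal constant-parameter segment to produce the final estimates.  When
simulation ground truth is available, per-segment percent errors are
computed by matching detected segments to true segments by maximal
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

from . import __version__ as _version
from .errors import EstimationError
from .model import MotionParameters, PiecewiseModel, Trajectory
from .localem import (
    KernelSpec,
    LocalEstimate,
    SegmentEstimate,
    MIN_SEGMENT_LENGTH,
    segment_em,
    sliding_window_scan,
)
from .changepoint import ChangePointSet, bic_order_select, detect_two_pass

__all__ = [
    "Stage1Config",
    "CDConfig",
    "Stage3Config",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "percent_error",
    "segments_from_changes",
]


@dataclass
class Stage1Config:
    """Sliding-window scan settings (kernel, stride, init policy)."""

    enabled: bool = True
    gamma: int = 1
    h: int = 200
    stride: int = 10
    init_policy: str = "warm"
    pinned: Dict[str, float] = field(default_factory=dict)
    tol: float = 1e-5
    max_iter: int = 100


@dataclass
class CDConfig:
    """Change-detection settings.

    ``p`` is the AR order or "auto" to select it by BIC (up to ``p_max``);
    ``lam`` the CUSUM threshold; ``h_cd`` the short-term model's window;
    ``match_tol`` the forward/backward pairing tolerance (defaults to
    ``h_cd``).  ``combine`` is "sum" (add per-axis likelihood-ratio
    increments) or "per-axis" (detect on each axis, union the results).
    """

    p: Union[int, str] = 1
    p_max: int = 10
    h_cd: int = 200
    lam: float = 2.1
    match_tol: Optional[int] = None
    include_intercept: bool = True
    combine: str = "sum"


@dataclass
class Stage3Config:
    """Per-segment EM settings."""

    gamma: int = 1
    tol: float = 1e-6
    max_iter: int = 200
    pinned: Dict[str, float] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    stage1: Stage1Config = field(default_factory=Stage1Config)
    cd: CDConfig = field(default_factory=CDConfig)
    stage3: Stage3Config = field(default_factory=Stage3Config)
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        return cls(
            stage1=Stage1Config(**d.get("stage1", {})),
            cd=CDConfig(**d.get("cd", {})),
            stage3=Stage3Config(**d.get("stage3", {})),
            seed=d.get("seed"),
        )

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        import json

        import yaml

        with open(path) as fh:
            text = fh.read()
        if path.endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class PipelineResult:
    """Everything one pipeline run produced, plus its provenance."""

    stage1_scan: Dict[str, List[LocalEstimate]]
    change_points: ChangePointSet
    segments: List[SegmentEstimate]
    ar_order: int
    n_steps: int
    dt: float
    config: PipelineConfig
    version: str = _version

    @property
    def change_times(self) -> List[int]:
        return self.change_points.times

    def segments_for_axis(self, axis: str) -> List[SegmentEstimate]:
        return [s for s in self.segments if s.axis_label == axis]


def percent_error(estimate: float, truth: float) -> Tuple[float, bool]:
    """Error of an estimate vs ground truth.

    Returns (error, relative): ``100 * |estimate - truth| / |truth|`` with
    ``relative=True`` when the truth is nonzero; the absolute error (same
    units as the parameter) with ``relative=False`` when the truth is
    exactly zero, where a relative error is undefined.
    """
    if truth == 0:
        return abs(estimate - truth), False
    return 100.0 * abs(estimate - truth) / abs(truth), True


def segments_from_changes(times: Sequence[int], n: int) -> List[Tuple[int, int]]:
    """Tile 1..n into maximal segments given change times.

    Each change time is the first step of a new regime, so the segments
    are [1, t1-1], [t1, t2-1], ..., [t_last, n].
    """
    starts = [1] + sorted(int(t) for t in times)
    bounds = []
    for i, s in enumerate(starts):
        e = starts[i + 1] - 1 if i + 1 < len(starts) else n
        if e < s:
            raise ValueError(f"change times {list(times)} do not tile 1..{n}")
        bounds.append((s, e))
    return bounds


def _overlap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def _truth_for_segment(model: PiecewiseModel, seg: Tuple[int, int]) -> MotionParameters:
    """Ground-truth parameters of the true segment with maximal overlap."""
    best, best_ov = None, -1
    for (s, e), (_, par) in zip(model.segment_bounds(), model.segments):
        ov = _overlap(seg, (s, e))
        if ov > best_ov:
            best, best_ov = par, ov
    return best


def run_pipeline(
    trajs: Union[Trajectory, Sequence[Trajectory]],
    config: Optional[PipelineConfig] = None,
    truth: Optional[PiecewiseModel] = None,
) -> PipelineResult:
    """Run the full three-stage analysis on one or more axes.

    All axes must share length and sampling interval; the change detector
    combines axes according to ``config.cd.combine`` while stages 1 and 3
    estimate each axis independently (per-axis motion independence).
    ``truth`` attaches percent errors to every estimated segment.
    """
    config = config or PipelineConfig()
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    trajs = list(trajs)
    if not trajs:
        raise EstimationError("no trajectory axes supplied")
    n = len(trajs[0])
    dt = trajs[0].dt
    for tr in trajs[1:]:
        if len(tr) != n or tr.dt != dt:
            raise EstimationError("all axes must share length and sampling interval")
    if n < MIN_SEGMENT_LENGTH:
        raise EstimationError(
            f"stage 3 needs at least {MIN_SEGMENT_LENGTH} samples, got {n}"
        )

    # ---- stage 1: sliding-window scan (advisory only) --------------------
    scan: Dict[str, List[LocalEstimate]] = {}
    if config.stage1.enabled:
        s1 = config.stage1
        kern = KernelSpec(gamma=s1.gamma, h=s1.h)
        for tr in trajs:
            scan[tr.axis_label] = sliding_window_scan(
                tr, kern, stride=s1.stride, pinned=s1.pinned,
                init_policy=s1.init_policy, tol=s1.tol, max_iter=s1.max_iter,
            )

    # ---- stage 2: change detection ---------------------------------------
    cd = config.cd
    ys = [tr.y for tr in trajs]
    if cd.p == "auto":
        p = max(bic_order_select(y, cd.p_max, cd.include_intercept)[0] for y in ys)
    else:
        p = int(cd.p)
    if n < cd.h_cd + p + 2:
        raise EstimationError(
            f"stage 2 needs more than h_cd + p + 2 = {cd.h_cd + p + 2} samples, got {n}"
        )
    if cd.combine == "sum":
        cps = detect_two_pass(
            ys, p, cd.h_cd, cd.lam, match_tol=cd.match_tol,
            include_intercept=cd.include_intercept,
        )
    elif cd.combine == "per-axis":
        from .changepoint import ChangePoint

        all_pts = []
        for y in ys:
            one = detect_two_pass(
                y, p, cd.h_cd, cd.lam, match_tol=cd.match_tol,
                include_intercept=cd.include_intercept,
            )
            all_pts.extend(one.points)
        all_pts.sort(key=lambda c: c.t_final)
        pruned = []
        for cp in all_pts:
            if pruned and cp.t_final - pruned[-1].t_final < cd.h_cd:
                continue
            pruned.append(cp)
        cps = ChangePointSet(points=pruned, lam=cd.lam, h_cd=cd.h_cd, p=p)
    else:
        raise ValueError("cd.combine must be 'sum' or 'per-axis'")

    # ---- stage 3: EM per segment -----------------------------------------
    s3 = config.stage3
    bounds = segments_from_changes(cps.times, n)
    segments: List[SegmentEstimate] = []
    for tr in trajs:
        for (s, e) in bounds:
            if e - s + 1 < MIN_SEGMENT_LENGTH:
                est = SegmentEstimate(
                    start=s, end=e, params=None, q=None, iterations=0,
                    converged=False, axis_label=tr.axis_label,
                )
            else:
                est = segment_em(
                    tr, s, e, gamma=s3.gamma, tol=s3.tol,
                    max_iter=s3.max_iter, pinned=s3.pinned,
                )
                est.axis_label = tr.axis_label
            if truth is not None and est.params is not None:
                tp = _truth_for_segment(truth, (s, e))
                est.percent_errors = {
                    "a": percent_error(est.params.a, tp.a),
                    "b": percent_error(est.params.b, tp.b),
                    "D": percent_error(est.params.D, tp.D),
                    "r": percent_error(est.params.r, tp.r),
                }
            segments.append(est)

    return PipelineResult(
        stage1_scan=scan,
        change_points=cps,
        segments=segments,
        ar_order=p,
        n_steps=n,
        dt=dt,
        config=config,
    )
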