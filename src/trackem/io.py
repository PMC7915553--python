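"""Trajectory and result I/O.

Trajectory CSV schema: header row with columns ``frame`` (consecutive
integers), ``t`` (seconds, uniformly spaced), then one position column per
axis (``x`` and optionally ``y``, ``z``) in micrometres.  A simulated
trajectory can be written together with a parallel ground-truth CSV
holding the latent positions and the active segment index per frame.

Result writers emit the per-stage CSVs (stage-1 scan, change points,
segment estimates) and a JSON run manifest with the exact configuration,
seed and software version, so every output is auditable.
"""

from __future__ import annotations

import json
import os
from typing import List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError
from .model import PiecewiseModel, Trajectory
from .pipeline import PipelineResult

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_ground_truth_csv",
    "write_results",
]

_AXIS_COLUMNS = ("x", "y", "z")
_REL_JITTER = 1e-9


def read_trajectory_csv(path: str) -> List[Trajectory]:
    """Read a trajectory CSV into one Trajectory per spatial axis.

    Enforces the constant-time-step assumption: gaps in ``frame`` or
    non-uniform ``t`` (beyond 1e-9 relative jitter) are schema errors.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as schema error
        raise SchemaError(f"cannot read trajectory CSV {path!r}: {exc}") from exc
    for col in ("frame", "t"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path!r}")
    axes = [c for c in _AXIS_COLUMNS if c in df.columns]
    if not axes:
        raise SchemaError(
            f"no position columns (one of {_AXIS_COLUMNS}) in {path!r}"
        )
    frames = df["frame"].to_numpy()
    if len(frames) < 2:
        raise SchemaError("trajectory must have at least 2 frames")
    if not np.array_equal(frames, frames[0] + np.arange(len(frames))):
        raise SchemaError(
            "gap or disorder in 'frame': the method assumes a constant time "
            "step between consecutive localizations (missing frames are not "
            "supported)"
        )
    t = df["t"].to_numpy(dtype=float)
    dts = np.diff(t)
    dt = float(np.median(dts))
    if dt <= 0 or np.any(np.abs(dts - dt) > _REL_JITTER * max(abs(dt), 1.0)):
        raise SchemaError(
            "non-uniform sampling in 't': the method assumes a constant time step"
        )
    out = []
    for ax in axes:
        vals = df[ax].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise SchemaError(f"NaN or infinite positions in column {ax!r}")
        out.append(Trajectory(y=vals, dt=dt, axis_label=ax))
    return out


def write_trajectory_csv(path: str, trajs: List[Trajectory]) -> None:
    """Write one or more axes to the trajectory CSV schema (full precision)."""
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    n = len(trajs[0])
    dt = trajs[0].dt
    data = {"frame": np.arange(1, n + 1), "t": np.arange(n) * dt}
    for tr in trajs:
        data[tr.axis_label] = tr.y
    pd.DataFrame(data).to_csv(path, index=False)


def write_ground_truth_csv(
    path: str, trajs: List[Trajectory], model: Optional[PiecewiseModel] = None
) -> None:
    """Write latent states (and the active segment index) per frame."""
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    n = len(trajs[0])
    data = {"frame": np.arange(1, n + 1)}
    for tr in trajs:
        if tr.x is None:
            raise ValueError(f"axis {tr.axis_label!r} has no latent states")
        data[f"x_true_{tr.axis_label}"] = tr.x
    if model is not None:
        data["segment"] = model.segment_index() + 1
    pd.DataFrame(data).to_csv(path, index=False)


def _scan_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for axis, ests in result.stage1_scan.items():
        for e in ests:
            rows.append(
                {
                    "axis": axis,
                    "t": e.t,
                    "a_hat": e.params.a,
                    "b_hat": e.params.b,
                    "D_hat": e.params.D,
                    "r_hat": e.params.r,
                    "iterations": e.iterations,
                    "converged": e.converged,
                }
            )
    return pd.DataFrame(rows)


def _changes_frame(result: PipelineResult) -> pd.DataFrame:
    rows = [
        {
            "t_forward": cp.t_forward,
            "t_backward": cp.t_backward,
            "t_final": cp.t_final,
            "matched": cp.matched,
        }
        for cp in result.change_points.points
    ]
    return pd.DataFrame(rows, columns=["t_forward", "t_backward", "t_final", "matched"])


def _segments_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for s in result.segments:
        row = {
            "axis": s.axis_label,
            "start": s.start,
            "end": s.end,
            "a_hat": s.params.a if s.params else np.nan,
            "b_hat": s.params.b if s.params else np.nan,
            "D_hat": s.params.D if s.params else np.nan,
            "r_hat": s.params.r if s.params else np.nan,
            "iterations": s.iterations,
            "converged": s.converged,
        }
        if s.percent_errors:
            for name, (val, rel) in s.percent_errors.items():
                row[f"{name}_pct_err"] = val if rel else np.nan
                row[f"{name}_abs_err"] = np.nan if rel else val
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(result: PipelineResult, outdir: str, seed: Optional[int] = None) -> None:
    """Write scan/change-point/segment CSVs and the JSON run manifest."""
    os.makedirs(outdir, exist_ok=True)
    if result.stage1_scan:
        _scan_frame(result).to_csv(os.path.join(outdir, "stage1_scan.csv"), index=False)
    _changes_frame(result).to_csv(os.path.join(outdir, "change_points.csv"), index=False)
    _segments_frame(result).to_csv(os.path.join(outdir, "segments.csv"), index=False)
    manifest = {
        "version": __version__,
        "seed": seed if seed is not None else result.config.seed,
        "n_steps": result.n_steps,
        "dt": result.dt,
        "ar_order": result.ar_order,
        "change_times": result.change_times,
        "config": result.config.to_dict(),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
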