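"""File formats and the end-to-end analysis pipeline.

TIFF stacks carry their physical calibration (pixel size, frame rate)
in a JSON sidecar next to the image file; tracks and run tables travel
as plain CSV so they stay inspectable and diff-able.  ``run_pipeline``
chains detection -> linking -> segmentation -> chemotaxis/motility
summary from a single config mapping and is deterministic given
(inputs, config).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import chemotaxis as _chemo
from . import runtumble as _rt
from . import tracking as _tracking
from .runtumble import RunSegment, SegmentationParams
from .tracking import ImageStack, Track

__all__ = [
    "read_stack", "write_stack",
    "read_tracks", "write_tracks",
    "read_runs", "write_runs",
    "parse_gradient_axis", "run_pipeline",
]

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]
RUN_COLUMNS = ["track_id", "start_frame", "end_frame", "T_s", "dx_um", "dy_um",
               "mean_speed_um_s", "alpha_rad", "class"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a uint16 TIFF plus a JSON metadata sidecar; returns the TIFF path."""
    path = Path(path)
    frames = stack.frames
    if frames.dtype != np.uint16:
        frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    _sidecar(path).write_text(json.dumps(
        {"pixel_size_um": stack.pixel_size, "frame_rate_fps": stack.frame_rate}))
    return path


def read_stack(path: str | Path,
               pixel_size: float | None = None,
               frame_rate: float | None = None) -> ImageStack:
    """Read a single-channel TIFF stack and its calibration.

    Calibration comes from the JSON sidecar when present; explicit
    arguments override it.  Missing calibration raises an error naming
    the missing field.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel stack, got shape {frames.shape}")
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    if pixel_size is None:
        pixel_size = meta.get("pixel_size_um")
    if frame_rate is None:
        frame_rate = meta.get("frame_rate_fps")
    if pixel_size is None:
        raise ValueError(f"{path}: missing pixel_size_um (no sidecar value or argument)")
    if frame_rate is None:
        raise ValueError(f"{path}: missing frame_rate_fps (no sidecar value or argument)")
    return ImageStack(frames, pixel_size=float(pixel_size), frame_rate=float(frame_rate))


def write_tracks(tracks: list[Track], path: str | Path) -> Path:
    """Write tracks as CSV (track_id, frame, t_s, x_um, y_um[, state, gap_filled])."""
    path = Path(path)
    rows = []
    any_state = any(tr.states is not None for tr in tracks)
    any_gap = any(tr.gap_filled is not None for tr in tracks)
    for tr in tracks:
        for i, (f, t) in enumerate(zip(tr.frames, tr.times)):
            row = {"track_id": tr.track_id, "frame": int(f), "t_s": t,
                   "x_um": tr.positions[i, 0], "y_um": tr.positions[i, 1]}
            if any_state:
                row["state"] = ("run" if tr.states[i] else "tumble") \
                    if tr.states is not None else ""
            if any_gap:
                row["gap_filled"] = bool(tr.gap_filled[i]) \
                    if tr.gap_filled is not None else False
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_tracks(path: str | Path, frame_rate: float | None = None) -> list[Track]:
    """Read a track CSV back into Track objects.

    Rows are sorted by (track_id, frame) on read; non-monotone frames
    within a track raise an error naming the track.  ``frame_rate`` is
    inferred from t_s = frame / frame_rate when not given.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df[TRACK_COLUMNS].isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 0-based index
        raise ValueError(f"{path}: malformed row at line {line}")
    df = df.sort_values(["track_id", "frame"], kind="stable")

    if frame_rate is None:
        nz = df[df["frame"] > 0]
        if len(nz) == 0 or (nz["t_s"] <= 0).any():
            raise ValueError(f"{path}: cannot infer frame_rate from t_s; pass it explicitly")
        frame_rate = float(np.median(nz["frame"] / nz["t_s"]))

    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        frames = grp["frame"].to_numpy(dtype=int)
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"{path}: track {tid} has non-monotone frames")
        states = None
        if "state" in grp.columns and grp["state"].notna().all():
            states = (grp["state"].astype(str) == "run").to_numpy()
        gap = None
        if "gap_filled" in grp.columns:
            gap = grp["gap_filled"].astype(bool).to_numpy()
        tracks.append(Track(track_id=int(tid), frames=frames,
                            positions=grp[["x_um", "y_um"]].to_numpy(dtype=float),
                            frame_rate=frame_rate, source="imported",
                            states=states, gap_filled=gap))
    return tracks


def write_runs(runs: list[RunSegment], path: str | Path) -> Path:
    """Write a run table CSV including the up/down/neither class."""
    rows = [{"track_id": r.track_id, "start_frame": r.start_frame,
             "end_frame": r.end_frame, "T_s": r.duration,
             "dx_um": r.displacement[0], "dy_um": r.displacement[1],
             "mean_speed_um_s": r.mean_speed, "alpha_rad": r.alpha,
             "class": r.direction_class} for r in runs]
    pd.DataFrame(rows, columns=RUN_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_runs(path: str | Path) -> list[RunSegment]:
    df = pd.read_csv(path)
    runs = []
    for _, r in df.iterrows():
        dur = float(r["T_s"])
        dx, dy = float(r["dx_um"]), float(r["dy_um"])
        runs.append(RunSegment(
            track_id=int(r["track_id"]), start_frame=int(r["start_frame"]),
            end_frame=int(r["end_frame"]), duration=dur,
            start=(np.nan, np.nan), end=(np.nan, np.nan),
            displacement=(dx, dy), mean_speed=float(r["mean_speed_um_s"]),
            alpha=float(r["alpha_rad"])))
    return runs


def parse_gradient_axis(axis) -> tuple[float, float]:
    """Parse 'x', 'y', an angle in radians, or a 2-vector into a unit vector."""
    if isinstance(axis, str):
        if axis == "x":
            return (1.0, 0.0)
        if axis == "y":
            return (0.0, 1.0)
        theta = float(axis)
        return (float(np.cos(theta)), float(np.sin(theta)))
    axis = np.asarray(axis, dtype=float)
    if axis.shape == ():
        return (float(np.cos(axis)), float(np.sin(axis)))
    n = np.hypot(axis[0], axis[1])
    return (float(axis[0] / n), float(axis[1] / n))


def run_pipeline(config: dict) -> dict:
    """Run the motility/chemotaxis pipeline from a config mapping.

    Config keys (all optional unless noted):

    - ``stack``: path to a TIFF stack, or ``tracks``: path to a track CSV
      (exactly one required)
    - ``pixel_size``, ``frame_rate``: calibration overrides for ``stack``
    - ``detection``: dict of detect_spots keyword arguments
    - ``max_disp`` (µm/frame, required with ``stack``), ``max_gap``
    - ``segmentation``: dict of SegmentationParams fields
    - ``gradient_axis``: "x", "y", angle (rad) or 2-vector; omit for a
      motility-only summary
    - ``d_threshold``: µm²/s active/passive split
    - ``out``: path for the summary JSON

    Returns the summary dict; failures carry the pipeline stage name.
    """
    if ("stack" in config) == ("tracks" in config):
        raise ValueError("config must provide exactly one of 'stack' or 'tracks'")

    try:
        if "stack" in config:
            stack = read_stack(config["stack"], config.get("pixel_size"),
                               config.get("frame_rate"))
            det_kw = dict(config.get("detection", {}))
            dets = {f: _tracking.detect_spots(stack.frames[f], stack.pixel_size, **det_kw)
                    for f in range(stack.n_frames)}
            tracks = _tracking.link(dets, max_disp=float(config["max_disp"]),
                                    frame_rate=stack.frame_rate,
                                    max_gap=int(config.get("max_gap", 0)))
        else:
            tracks = read_tracks(config["tracks"], config.get("frame_rate"))
        if not tracks:
            raise ValueError("no tracks found")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'tracking': {e}") from e

    seg = SegmentationParams(**config.get("segmentation", {}))
    axis = parse_gradient_axis(config.get("gradient_axis", "y"))
    min_run_s = seg.min_run_frames / tracks[0].frame_rate
    logger.info("min_run_frames=%d (%.3f s at %.1f fps)", seg.min_run_frames,
                min_run_s, tracks[0].frame_rate)

    try:
        runs: list[RunSegment] = []
        for tr in tracks:
            r, _ = _rt.segment_runs(tr, seg, gradient_axis=axis)
            runs.extend(r)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'segmentation': {e}") from e

    d_thr = float(config.get("d_threshold", _tracking.DEFAULT_D_THRESHOLD))
    summary: dict = {"n_tracks": len(tracks), "n_runs": len(runs),
                     "d_threshold_um2_s": d_thr}
    try:
        long_enough = [t for t in tracks if len(t) > 10]
        if long_enough:
            _, _, motile_fraction = _tracking.classify_population(long_enough, d_thr)
            summary["motile_fraction"] = motile_fraction
        if runs:
            mean_d, median_d, _ = _rt.run_duration_stats(runs)
            summary["mean_run_duration_s"] = mean_d
            summary["median_run_duration_s"] = median_d
            summary["population_speed_um_s"] = _rt.population_speed(runs)
        if "gradient_axis" in config and runs:
            cs = _chemo.chemotaxis_summary(tracks, runs, gradient_axis=axis)
            summary.update(cs.to_dict())
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'summary': {e}") from e

    logger.info("summary: %s", summary)
    if "out" in config:
        Path(config["out"]).write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
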