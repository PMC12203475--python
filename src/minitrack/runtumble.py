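"""Run/tumble segmentation of swimmer trajectories and per-run kinematics.

A trajectory is partitioned into runs (persistent near-straight motion)
and tumbles (brief reorientation events) using a two-criterion rule: a
frame is a tumble when the smoothed instantaneous speed drops below a
fraction of the track's median speed, or when the turning rate spikes
above a threshold.  Maximal tumble-free intervals become
:class:`RunSegment` objects carrying duration, displacement, mean speed
and the direction angle

    alpha = arccos( g . d / |d| )   in [0, pi],

the angle between the run displacement ``d`` and the attractant
gradient axis ``g``.  With the gradient along +y this reduces to
``alpha = arccos( dy / sqrt(dx^2 + dy^2) )``.  Runs shorter than 5
frames (0.1 s at 50 fps) are discarded by default before duration
statistics.  Runs are classed "up" the gradient when ``alpha < pi/4``
and "down" when ``3*pi/4 < alpha < pi`` (strict inequalities; the
boundary cones are "neither").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tracking import Track

__all__ = [
    "RunSegment",
    "SegmentationParams",
    "segment_runs",
    "filter_runs",
    "run_direction",
    "classify_direction",
    "run_duration_stats",
    "population_speed",
]

logger = logging.getLogger(__name__)


@dataclass
class RunSegment:
    """One tumble-free interval of a track."""

    track_id: int
    start_frame: int
    end_frame: int
    duration: float          # s, (end_frame - start_frame) / frame_rate
    start: tuple[float, float]   # µm
    end: tuple[float, float]     # µm
    displacement: tuple[float, float]  # µm
    mean_speed: float        # µm/s, mean instantaneous speed over the run
    alpha: float             # rad in [0, pi], vs. gradient axis

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    @property
    def direction_class(self) -> str:
        return classify_direction(self.alpha)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable thresholds for run/tumble classification.

    speed_drop_fraction : tumble when smoothed speed < fraction * median speed
    turn_rate_threshold : rad/s, tumble when |turning rate| exceeds this
    smoothing_window : frames, moving-average window for speed and heading
    min_run_frames : runs spanning fewer frames are removed (default 5,
        i.e. 0.1 s at 50 fps)
    """

    speed_drop_fraction: float = 0.5
    turn_rate_threshold: float = 25.0
    smoothing_window: int = 3
    min_run_frames: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.speed_drop_fraction < 1:
            raise ValueError("speed_drop_fraction must lie in (0, 1)")
        if self.min_run_frames < 1:
            raise ValueError("min_run_frames must be >= 1")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(x) < window:
        return x
    kernel = np.ones(window) / window
    # reflect-pad so the output has the input length without edge bias
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def segment_runs(track: Track,
                 p: SegmentationParams = SegmentationParams(),
                 gradient_axis: tuple[float, float] = (0.0, 1.0),
                 apply_min_filter: bool = True
                 ) -> tuple[list[RunSegment], list[tuple[int, int]]]:
    """Partition a track into runs and tumbles.

    Returns (runs, tumble_intervals); tumble intervals are
    (start_frame, end_frame) pairs.  Tracks shorter than
    ``2 * min_run_frames`` points are skipped with a warning and yield
    no segments.  Every frame of the track belongs to exactly one run or
    tumble interval.
    """
    if len(track) < 2 * p.min_run_frames:
        logger.warning("track %s shorter than %d frames; skipped",
                       track.track_id, 2 * p.min_run_frames)
        return [], []

    pos = track.positions
    dt = 1.0 / track.frame_rate
    steps = np.diff(pos, axis=0)
    speeds = np.hypot(steps[:, 0], steps[:, 1]) / dt  # per step
    sm_speed = _smooth(speeds, p.smoothing_window)

    headings = np.arctan2(steps[:, 1], steps[:, 0])
    dtheta = np.angle(np.exp(1j * np.diff(headings)))  # wrapped heading change
    turn_rate = np.abs(dtheta) / dt
    sm_turn = _smooth(turn_rate, p.smoothing_window)

    median_speed = float(np.median(sm_speed))
    # per-step tumble mask; step i covers frames i -> i+1
    step_tumble = sm_speed < p.speed_drop_fraction * median_speed
    # turn rate i is the change between step i and i+1; flag both steps
    spike = sm_turn > p.turn_rate_threshold
    step_tumble[:-1] |= spike
    step_tumble[1:] |= spike

    # point labels: a point is a tumble if any adjacent step is a tumble step
    n = len(track)
    point_tumble = np.zeros(n, dtype=bool)
    point_tumble[:-1] |= step_tumble
    point_tumble[1:] |= step_tumble

    runs: list[RunSegment] = []
    tumbles: list[tuple[int, int]] = []
    frames = track.frames
    i = 0
    while i < n:
        j = i
        while j + 1 < n and point_tumble[j + 1] == point_tumble[i]:
            j += 1
        if point_tumble[i]:
            tumbles.append((int(frames[i]), int(frames[j])))
        elif j > i:
            runs.append(_make_segment(track, i, j, gradient_axis))
        else:  # isolated single run point: fold into tumbles
            tumbles.append((int(frames[i]), int(frames[i])))
        i = j + 1

    if apply_min_filter:
        runs = filter_runs(runs, p.min_run_frames)
    return runs, tumbles


def _make_segment(track: Track, i: int, j: int,
                  gradient_axis: tuple[float, float]) -> RunSegment:
    pos = track.positions
    frames = track.frames
    dt = 1.0 / track.frame_rate
    steps = np.diff(pos[i:j + 1], axis=0)
    speeds = np.hypot(steps[:, 0], steps[:, 1]) / dt
    d = pos[j] - pos[i]
    disp_norm = np.hypot(d[0], d[1])
    alpha = run_direction_from_displacement(d, gradient_axis) if disp_norm > 0 else np.nan
    return RunSegment(
        track_id=track.track_id,
        start_frame=int(frames[i]),
        end_frame=int(frames[j]),
        duration=float(frames[j] - frames[i]) / track.frame_rate,
        start=(float(pos[i, 0]), float(pos[i, 1])),
        end=(float(pos[j, 0]), float(pos[j, 1])),
        displacement=(float(d[0]), float(d[1])),
        mean_speed=float(np.mean(speeds)),
        alpha=float(alpha),
    )


def filter_runs(runs: list[RunSegment], min_run_frames: int = 5) -> list[RunSegment]:
    """Drop runs spanning fewer than ``min_run_frames`` frames.

    The threshold is strict ("shorter than"): a run of exactly
    ``min_run_frames`` frames is retained.  Order preserved; idempotent.
    """
    return [r for r in runs if r.n_frames >= min_run_frames]


def run_direction_from_displacement(displacement,
                                    gradient_axis=(0.0, 1.0)) -> float:
    """alpha = arccos(g . d / |d|) in [0, pi] for displacement d, axis g."""
    d = np.asarray(displacement, dtype=float)
    norm = np.hypot(d[0], d[1])
    if norm == 0:
        raise ValueError("zero displacement: run direction undefined")
    g = np.asarray(gradient_axis, dtype=float)
    g = g / np.hypot(g[0], g[1])
    return float(np.arccos(np.clip((g @ d) / norm, -1.0, 1.0)))


def run_direction(run: RunSegment, gradient_axis=(0.0, 1.0)) -> float:
    """Direction angle of a run relative to the gradient axis, rad in [0, pi]."""
    return run_direction_from_displacement(run.displacement, gradient_axis)


def classify_direction(alpha: float) -> str:
    """"up" if alpha < pi/4, "down" if 3*pi/4 < alpha < pi, else "neither"."""
    if np.isnan(alpha):
        return "neither"
    if alpha < np.pi / 4:
        return "up"
    if 3 * np.pi / 4 < alpha < np.pi:
        return "down"
    return "neither"


def run_duration_stats(runs: list[RunSegment],
                       bins: int | np.ndarray = 20
                       ) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Plain arithmetic mean and median of run durations, plus a histogram.

    Returns (mean_s, median_s, (counts, bin_edges)).
    """
    if not runs:
        raise ValueError("run_duration_stats requires at least one run")
    durations = np.array([r.duration for r in runs])
    counts, edges = np.histogram(durations, bins=bins)
    return float(durations.mean()), float(np.median(durations)), (counts, edges)


def population_speed(runs: list[RunSegment]) -> float:
    """Population swimming speed, µm/s.

    Average instantaneous (frame-to-frame) speed pooled over all frames
    inside classified runs — equivalently the step-count-weighted mean
    of per-run mean speeds.
    """
    if not runs:
        raise ValueError("population_speed requires at least one run")
    weights = np.array([r.n_frames for r in runs], dtype=float)
    speeds = np.array([r.mean_speed for r in runs])
    if weights.sum() == 0:
        raise ValueError("population_speed requires runs spanning >= 2 frames")
    return float(np.average(speeds, weights=weights))
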