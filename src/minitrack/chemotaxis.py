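"""Population chemotaxis statistics: drift velocity, bias, efficiency,
direction-conditioned run durations, and accumulation counting.

The chemotactic drift velocity along a gradient axis is the
duration-weighted mean of per-trajectory end-to-end velocities,

    V_X,i = (X_end,i - X_start,i) / T_i,
    V_X   = sum_i V_X,i * T_i / sum_i T_i,

which is algebraically the total axis displacement divided by the total
tracked time.  T_i is the whole-trajectory wall-clock duration,
including tumbles and any gap-filled frames.  Dividing by the population
swimming speed V (mean instantaneous speed within classified runs)
yields the chemotactic bias V_X/V, and by V² the chemotactic
efficiency V_X/V² (s/µm) — the drift per unit of propulsion invested.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .runtumble import RunSegment, population_speed
from .tracking import Track, detect_spots

__all__ = ["ChemotaxisSummary", "drift_velocity", "chemotaxis_summary",
           "accumulation_count"]


@dataclass
class ChemotaxisSummary:
    """Population-level chemotaxis readout.

    V_X : µm/s drift along the gradient axis
    V : µm/s population swimming speed within runs
    bias : V_X / V (dimensionless)
    efficiency : V_X / V² (s/µm)
    mean_run_up / mean_run_down : s, mean run duration in the up/down
        cones (None when a cone is empty — missing, not zero)
    """

    V_X: float
    V: float
    bias: float
    efficiency: float
    mean_run_up: float | None
    mean_run_down: float | None
    n_trajectories: int
    n_runs_up: int
    n_runs_down: int

    def to_dict(self) -> dict:
        return asdict(self)


def _axis_unit(gradient_axis) -> np.ndarray:
    g = np.asarray(gradient_axis, dtype=float)
    n = np.hypot(g[0], g[1])
    if n == 0:
        raise ValueError("gradient_axis must be nonzero")
    return g / n


def drift_velocity(tracks: list[Track], gradient_axis=(0.0, 1.0)) -> float:
    """Duration-weighted population drift velocity along the gradient, µm/s.

    Per-track drift is the gradient-axis component of (end - start)/T;
    weighting each by its duration T_i makes the population value equal
    to (sum of axis displacements) / (sum of durations) exactly.
    """
    if not tracks:
        raise ValueError("drift_velocity requires at least one track")
    g = _axis_unit(gradient_axis)
    total_disp = 0.0
    total_time = 0.0
    for tr in tracks:
        t = tr.duration
        if t <= 0:
            raise ValueError(f"track {tr.track_id} has zero duration")
        total_disp += float((tr.positions[-1] - tr.positions[0]) @ g)
        total_time += t
    return total_disp / total_time


def chemotaxis_summary(tracks: list[Track],
                       runs: list[RunSegment],
                       gradient_axis=(0.0, 1.0)) -> ChemotaxisSummary:
    """Full population summary from tracks and their segmented runs.

    Runs in the "neither" angular band contribute to V (and the tracks
    to V_X) but not to the up/down duration means; an empty direction
    class reports its mean as None.
    """
    v_x = drift_velocity(tracks, gradient_axis)
    v = population_speed(runs)

    up = [r.duration for r in runs if r.direction_class == "up"]
    down = [r.duration for r in runs if r.direction_class == "down"]

    return ChemotaxisSummary(
        V_X=v_x,
        V=v,
        bias=v_x / v,
        efficiency=v_x / v ** 2,
        mean_run_up=float(np.mean(up)) if up else None,
        mean_run_down=float(np.mean(down)) if down else None,
        n_trajectories=len(tracks),
        n_runs_up=len(up),
        n_runs_down=len(down),
    )


def accumulation_count(snapshot: np.ndarray,
                       pixel_size: float = 1.0,
                       min_sigma: float = 1.0,
                       max_sigma: float = 3.0,
                       threshold: float = 5.0,
                       exclusion_mask: np.ndarray | None = None) -> int:
    """Count fluorescent particles in a single snapshot frame.

    Spots are detected with :func:`minitrack.tracking.detect_spots`;
    detections falling inside ``exclusion_mask`` (boolean, True =
    excluded, e.g. particles stuck to elongated parental cells) are not
    counted.  A blank frame counts 0.
    """
    spots = detect_spots(snapshot, pixel_size=pixel_size, min_sigma=min_sigma,
                         max_sigma=max_sigma, threshold=threshold)
    if len(spots) == 0:
        return 0
    if exclusion_mask is None:
        return len(spots)
    mask = np.asarray(exclusion_mask, dtype=bool)
    if mask.shape != snapshot.shape:
        raise ValueError("exclusion_mask shape must match snapshot")
    cols = np.clip(np.round(spots[:, 0] / pixel_size).astype(int), 0, mask.shape[1] - 1)
    rows = np.clip(np.round(spots[:, 1] / pixel_size).astype(int), 0, mask.shape[0] - 1)
    return int(np.sum(~mask[rows, cols]))
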