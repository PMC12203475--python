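"""Spot detection, trajectory linking and diffusion-based motility classification.

Particles are detected frame by frame as blob-like intensity maxima,
linked into trajectories by gated greedy nearest-neighbour assignment,
and classified as actively propelled or passively diffusing by
thresholding the diffusion coefficient fitted to the time-averaged
mean-squared displacement (MSD).  The MSD of a 2-D Brownian walker is
linear in lag time with slope 4D; self-propelled swimmers are
super-diffusive on short lags, so their apparent D lies far above the
Brownian value and a simple threshold separates the two populations.

All positions leave this module in micrometres; pixel units never
escape.  Coordinates use the image convention: origin at the centre of
the top-left pixel, x rightward (columns), y downward (rows), frames
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

__all__ = [
    "ImageStack",
    "Track",
    "DiffusionEstimate",
    "DEFAULT_D_THRESHOLD",
    "theoretical_bead_diffusion",
    "detect_spots",
    "link",
    "estimate_diffusion",
    "classify_population",
]

_KB = 1.380649e-23  # J/K


def theoretical_bead_diffusion(diameter_um: float = 1.4,
                               temperature_c: float = 22.5,
                               viscosity_pa_s: float = 0.947e-3) -> float:
    """Stokes-Einstein diffusion coefficient of a sphere in water, µm²/s.

    Defaults describe the 1.4 µm streptavidin-coated cargo beads at the
    22.5 °C assay temperature (water viscosity 0.947 mPa·s).
    """
    r_m = 0.5 * diameter_um * 1e-6
    d_m2_s = _KB * (temperature_c + 273.15) / (6.0 * np.pi * viscosity_pa_s * r_m)
    return d_m2_s * 1e12


#: Active/passive split: 5x the Brownian D of a free 1.4 µm bead (~1.6 µm²/s).
DEFAULT_D_THRESHOLD = 5.0 * theoretical_bead_diffusion()


@dataclass
class ImageStack:
    """A single-channel time-lapse movie with physical calibration.

    frames : (T, H, W) intensity array, T >= 2
    pixel_size : µm per pixel
    frame_rate : frames per second
    """

    frames: np.ndarray
    pixel_size: float
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("ImageStack requires at least 2 frames")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.frames.shape


@dataclass
class Track:
    """Time-ordered positions of one particle.

    frames : strictly increasing integer frame indices
    positions : (n, 2) array of (x, y) in µm
    frame_rate : frames per second (times = frames / frame_rate)
    source : one of {"detected", "imported", "synthetic"}
    states : optional boolean run mask (True = run) for synthetic ground truth
    gap_filled : optional boolean mask marking interpolated frames
    """

    track_id: int
    frames: np.ndarray
    positions: np.ndarray
    frame_rate: float
    source: str = "detected"
    states: np.ndarray | None = None
    gap_filled: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.frames) < 2:
            raise ValueError("Track requires at least 2 points")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id}: frames must be strictly increasing")
        if self.positions.shape != (len(self.frames), 2):
            raise ValueError("positions must be (n, 2) matching frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def times(self) -> np.ndarray:
        """Times in seconds, frames / frame_rate."""
        return self.frames / self.frame_rate

    @property
    def duration(self) -> float:
        """Wall-clock duration first-to-last frame, s."""
        return (self.frames[-1] - self.frames[0]) / self.frame_rate

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class DiffusionEstimate:
    """MSD line-fit result for one track."""

    D: float                 # µm²/s, slope/4
    msd_lags_used: int
    fit_intercept: float     # µm², localization-noise offset
    is_active: bool


def detect_spots(frame: np.ndarray,
                 pixel_size: float,
                 min_sigma: float = 1.0,
                 max_sigma: float = 3.0,
                 threshold: float = 5.0,
                 return_sigma: bool = False) -> np.ndarray:
    """Detect blob-like spots in one frame; sub-pixel centroids in µm.

    The frame is smoothed at ``min_sigma``, local maxima exceeding
    ``background + threshold`` are kept (deduplicated within 1 px), and
    each is refined to a background-subtracted intensity-weighted
    centroid in a window of radius 2*max_sigma (wide enough for >95% of
    the spot mass, narrow enough not to swallow neighbours).  A blank or flat frame
    yields an empty array, not an error.

    Returns (n, 2) array of (x, y) µm, or (n, 3) of (x, y, sigma_px)
    when ``return_sigma`` — sigma is the RMS radius of the spot, usable
    as a crude size proxy.
    """
    if min_sigma > max_sigma:
        raise ValueError("min_sigma must be <= max_sigma")
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("detect_spots expects a 2-D frame")

    background = np.median(frame)
    smoothed = ndimage.gaussian_filter(frame, sigma=min_sigma)
    if smoothed.max() - smoothed.min() == 0:
        return np.empty((0, 3 if return_sigma else 2))

    peaks = peak_local_max(smoothed, min_distance=2,
                           threshold_abs=background + threshold)
    if len(peaks) == 0:
        return np.empty((0, 3 if return_sigma else 2))

    h, w = frame.shape
    radius = int(np.ceil(2 * max_sigma))
    out = []
    for r, c in peaks:
        r0, r1 = max(0, r - radius), min(h, r + radius + 1)
        c0, c1 = max(0, c - radius), min(w, c + radius + 1)
        window = frame[r0:r1, c0:c1] - background
        window = np.clip(window, 0, None)
        total = window.sum()
        if total <= 0:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        yc = (rr * window).sum() / total
        xc = (cc * window).sum() / total
        if return_sigma:
            var = (((rr - yc) ** 2 + (cc - xc) ** 2) * window).sum() / total
            out.append((xc, yc, np.sqrt(var / 2.0)))
        else:
            out.append((xc, yc))
    if not out:
        return np.empty((0, 3 if return_sigma else 2))
    out = np.asarray(out)

    # deduplicate refined centroids closer than 1 px, keep first (brighter peak)
    keep = np.ones(len(out), dtype=bool)
    for i in range(len(out)):
        if not keep[i]:
            continue
        d = np.hypot(out[i + 1:, 0] - out[i, 0], out[i + 1:, 1] - out[i, 1])
        keep[i + 1:] &= d >= 1.0
    out = out[keep]

    out[:, :2] *= pixel_size
    return out


def link(detections: dict[int, np.ndarray] | list[np.ndarray],
         max_disp: float,
         frame_rate: float,
         max_gap: int = 0,
         min_length: int = 2) -> list[Track]:
    """Link per-frame detections into trajectories.

    Gated greedy nearest-neighbour assignment: candidate pairs between
    open tracks and current-frame detections are matched in order of
    increasing distance, each end used at most once, within a gate of
    ``max_disp * (gap + 1)`` µm.  Tracks may bridge up to ``max_gap``
    missing frames; bridged frames get linearly interpolated positions
    flagged gap_filled.  Unmatched detections start new tracks.

    detections : mapping frame -> (n, 2) µm positions (or a list indexed
        by frame)
    """
    if isinstance(detections, list):
        detections = {f: d for f, d in enumerate(detections)}

    open_tracks: list[dict] = []   # {"frames": [...], "pos": [...], "last_frame": int}
    closed: list[dict] = []

    for f in sorted(detections):
        dets = np.asarray(detections[f], dtype=float).reshape(-1, 2)

        # retire tracks whose gap exceeded the allowance
        still = []
        for tr in open_tracks:
            if f - tr["frames"][-1] > max_gap + 1:
                closed.append(tr)
            else:
                still.append(tr)
        open_tracks = still

        assigned_det = np.zeros(len(dets), dtype=bool)
        if open_tracks and len(dets):
            pairs = []
            for ti, tr in enumerate(open_tracks):
                gap = f - tr["frames"][-1] - 1
                gate = max_disp * (gap + 1)
                last = tr["pos"][-1]
                d = np.hypot(dets[:, 0] - last[0], dets[:, 1] - last[1])
                for di in np.flatnonzero(d <= gate):
                    pairs.append((d[di], ti, di))
            pairs.sort()
            used_tr = set()
            for dist, ti, di in pairs:
                if ti in used_tr or assigned_det[di]:
                    continue
                used_tr.add(ti)
                assigned_det[di] = True
                tr = open_tracks[ti]
                gap = f - tr["frames"][-1] - 1
                if gap > 0:  # bridge with interpolated, flagged positions
                    p0 = np.asarray(tr["pos"][-1])
                    p1 = dets[di]
                    for k in range(1, gap + 1):
                        frac = k / (gap + 1)
                        tr["frames"].append(tr["frames"][-1] + 1)
                        tr["pos"].append(tuple(p0 + frac * (p1 - p0)))
                        tr["gap"].append(True)
                tr["frames"].append(f)
                tr["pos"].append(tuple(dets[di]))
                tr["gap"].append(False)

        for di in np.flatnonzero(~assigned_det):
            open_tracks.append({"frames": [f], "pos": [tuple(dets[di])], "gap": [False]})

    closed.extend(open_tracks)

    tracks = []
    tid = 0
    for tr in closed:
        if len(tr["frames"]) < min_length:
            continue
        tracks.append(Track(track_id=tid,
                            frames=np.asarray(tr["frames"]),
                            positions=np.asarray(tr["pos"]),
                            frame_rate=frame_rate,
                            source="detected",
                            gap_filled=np.asarray(tr["gap"], dtype=bool)))
        tid += 1
    return tracks


def time_averaged_msd(track: Track, n_lags: int) -> np.ndarray:
    """Time-averaged MSD over lags 1..n_lags, µm²."""
    pos = track.positions
    msd = np.empty(n_lags)
    for lag in range(1, n_lags + 1):
        d = pos[lag:] - pos[:-lag]
        msd[lag - 1] = np.mean(np.sum(d * d, axis=1))
    return msd


def estimate_diffusion(track: Track,
                       n_lags: int = 10,
                       d_threshold: float = DEFAULT_D_THRESHOLD) -> DiffusionEstimate:
    """Fit D from the time-averaged MSD of one track.

    A least-squares line through (lag time, MSD) over lags 1..n_lags
    gives D = slope/4 (2-D); the intercept absorbs localization noise.
    ``is_active`` flags D above the Brownian threshold.
    """
    if n_lags < 2:
        raise ValueError("n_lags must be >= 2")
    if len(track) <= n_lags:
        raise ValueError(
            f"track {track.track_id} too short: need > {n_lags} points, got {len(track)}")
    msd = time_averaged_msd(track, n_lags)
    tau = np.arange(1, n_lags + 1) / track.frame_rate
    slope, intercept = np.polyfit(tau, msd, 1)
    d = slope / 4.0
    return DiffusionEstimate(D=d, msd_lags_used=n_lags, fit_intercept=intercept,
                             is_active=bool(d > d_threshold))


def classify_population(tracks: list[Track],
                        d_threshold: float = DEFAULT_D_THRESHOLD,
                        n_lags: int = 10) -> tuple[list[Track], list[Track], float]:
    """Partition tracks into (active, passive) by the diffusion threshold.

    Returns (active, passive, motile_fraction) with
    motile_fraction = |active| / |tracks|.
    """
    if not tracks:
        raise ValueError("classify_population requires at least one track")
    active, passive = [], []
    for tr in tracks:
        est = estimate_diffusion(tr, n_lags=n_lags, d_threshold=d_threshold)
        (active if est.is_active else passive).append(tr)
    return active, passive, len(active) / len(tracks)
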