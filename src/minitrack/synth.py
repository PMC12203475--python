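"""Ground-truthed synthetic data: run-and-tumble swimmers, Brownian beads,
rendered spot movies, and oscillating intensity traces.

The generator emulates the statistical structure the analysis stages
assume so that every stage is testable without raw microscopy:

* **Swimmers** alternate ballistic runs (constant speed, rotational
  diffusion of the heading) with tumbles (near-stationary jitter at 10%
  of run speed followed by a Gaussian reorientation).  Run durations are
  exponential with mean ``mean_run_duration * (1 + kappa * cos(alpha))``
  where ``alpha`` is the angle between the heading at run start and the
  attractant-gradient axis — the minimal generative mechanism producing
  the "runs extended up the gradient" chemotaxis signature.  ``kappa``
  is a dimensionless modulation depth; 0 gives an unbiased swimmer.
* **Beads** are free 2-D Brownian walkers with per-axis increment
  variance 2*D*dt.
* **Rendering** paints isotropic Gaussian spots plus additive Gaussian
  noise onto a pixel grid at a configurable frame rate and pixel size
  (the acquisitions being emulated ran at 50 fps phase contrast and
  56 fps fluorescence).
* **Rotation traces** superpose a sinusoid at a known flagellar
  frequency on a Brownian (1/omega^2 power spectrum) background.

Every operation is bit-reproducible given its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import ImageStack, Track

__all__ = [
    "SwimmerParams",
    "BeadParams",
    "RenderParams",
    "OscillationParams",
    "simulate_run_tumble",
    "simulate_beads",
    "render_movie",
    "synth_rotation_trace",
    "synth_rotation_movie",
    "ground_truth_drift",
]

#: tumble jitter speed as a fraction of run speed
TUMBLE_JITTER_FRACTION = 0.1


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class SwimmerParams:
    """Generative parameters for a run-and-tumble swimmer population.

    speed : µm/s, constant swimming speed during runs
    mean_run_duration : s, exponential mean at alpha = 90 deg
    mean_tumble_duration : s, exponential mean (0 = instantaneous reorientation)
    rotational_diffusion : rad²/s, heading diffusion during runs
    tumble_angle_spread : rad, std of the Gaussian reorientation at tumble end
        (wrapped to (-pi, pi])
    chemotactic_modulation : kappa >= 0, run-duration bias depth along the gradient
    gradient_axis : unit vector (x, y) of the attractant gradient
    arena : (width, height) µm rectangle
    boundary : "reflect" (default, keeps density uniform) or "absorb"
    dt : s, integration and sampling step (default 0.02 s = 50 fps)
    duration : s, total simulated time
    """

    speed: float = 15.0
    mean_run_duration: float = 1.0
    mean_tumble_duration: float = 0.1
    rotational_diffusion: float = 0.1
    tumble_angle_spread: float = 1.2
    chemotactic_modulation: float = 0.0
    gradient_axis: tuple[float, float] = (0.0, 1.0)
    arena: tuple[float, float] = (2000.0, 2000.0)
    boundary: str = "reflect"
    n_swimmers: int = 1
    dt: float = 0.02
    duration: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.speed > 0, "speed", "must be > 0")
        _require(self.mean_run_duration > 0, "mean_run_duration", "must be > 0")
        _require(self.mean_tumble_duration >= 0, "mean_tumble_duration", "must be >= 0")
        _require(self.rotational_diffusion >= 0, "rotational_diffusion", "must be >= 0")
        _require(self.chemotactic_modulation >= 0, "chemotactic_modulation", "must be >= 0")
        _require(self.dt > 0, "dt", "must be > 0")
        _require(self.dt < self.mean_run_duration / 5,
                 "dt", "must be < mean_run_duration / 5")
        _require(self.arena[0] > 0 and self.arena[1] > 0, "arena", "sides must be > 0")
        _require(self.n_swimmers >= 1, "n_swimmers", "must be >= 1")
        _require(self.duration > 0, "duration", "must be > 0")
        _require(self.boundary in ("reflect", "absorb"), "boundary",
                 "must be 'reflect' or 'absorb'")


@dataclass(frozen=True)
class BeadParams:
    """Free Brownian beads: diffusion_coefficient µm²/s, arena for seeding only."""

    diffusion_coefficient: float = 0.35
    n_beads: int = 1
    dt: float = 0.02
    duration: float = 10.0
    arena: tuple[float, float] = (2000.0, 2000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.diffusion_coefficient >= 0, "diffusion_coefficient", "must be >= 0")
        _require(self.n_beads >= 1, "n_beads", "must be >= 1")
        _require(self.dt > 0, "dt", "must be > 0")
        _require(self.duration > 0, "duration", "must be > 0")


@dataclass(frozen=True)
class RenderParams:
    """Rendering of point particles as Gaussian spots on a noisy detector."""

    pixel_size: float = 0.5        # µm/px
    image_shape: tuple[int, int] = (256, 256)  # (H, W) px
    psf_sigma: float = 1.5         # px
    spot_amplitude: float = 200.0  # intensity units above background
    background: float = 100.0
    noise_sd: float = 20.0
    frame_rate: float = 50.0
    out_of_view: str = "clip"      # "clip" drops off-frame spots; "error" raises
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.pixel_size > 0, "pixel_size", "must be > 0")
        _require(self.psf_sigma > 0, "psf_sigma", "must be > 0")
        _require(self.frame_rate > 0, "frame_rate", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.out_of_view in ("clip", "error"), "out_of_view",
                 "must be 'clip' or 'error'")


@dataclass(frozen=True)
class OscillationParams:
    """A periodic intensity signal on a Brownian background.

    frequency : Hz, must lie below Nyquist (frame_rate/2)
    amplitude : intensity units of the sinusoid
    brownian_background_D : intensity²/s, variance rate of the random-walk
        background (its power spectrum falls as 1/omega²)
    frame_rate : frames/s (default 56, the fluorescence acquisition rate)
    n_frames : samples, a power of two (default 128)
    """

    frequency: float = 14.0
    amplitude: float = 1.0
    brownian_background_D: float = 0.05
    frame_rate: float = 56.0
    n_frames: int = 128
    offset: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.frame_rate > 0, "frame_rate", "must be > 0")
        _require(0 < self.frequency < self.frame_rate / 2, "frequency",
                 "must lie in (0, Nyquist)")
        _require(self.amplitude >= 0, "amplitude", "must be >= 0")
        _require(self.brownian_background_D >= 0, "brownian_background_D", "must be >= 0")
        _require(self.n_frames >= 8 and (self.n_frames & (self.n_frames - 1)) == 0,
                 "n_frames", "must be a power of two >= 8")


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.hypot(v[0], v[1])
    if n == 0:
        raise ValueError("gradient_axis: must be nonzero")
    return v / n


def _reflect(pos: np.ndarray, theta: np.ndarray, arena: tuple[float, float]) -> None:
    """Reflect positions at the arena walls in place, mirroring headings."""
    w, h = arena
    for axis, lim in ((0, w), (1, h)):
        low = pos[:, axis] < 0
        high = pos[:, axis] > lim
        pos[low, axis] *= -1
        pos[high, axis] = 2 * lim - pos[high, axis]
        hit = low | high
        if np.any(hit):
            if axis == 0:
                theta[hit] = np.pi - theta[hit]
            else:
                theta[hit] = -theta[hit]


def simulate_run_tumble(params: SwimmerParams) -> list[Track]:
    """Simulate a run-and-tumble swimmer population.

    Returns one :class:`Track` per swimmer sampled every ``dt``, with
    ``states`` carrying the ground-truth per-point run mask (True during
    runs).  Run durations are drawn from an exponential whose mean is
    modulated by the heading at run start,
    ``mean_run_duration * (1 + kappa * cos(alpha))``, truncated below at
    ``dt``; tumbles jitter at 10% of run speed and end with a Gaussian
    heading kick.  Identical parameters (including seed) give identical
    output.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_swimmers
    n_steps = int(round(params.duration / params.dt))
    dt = params.dt
    g = _unit(params.gradient_axis)
    theta_g = np.arctan2(g[1], g[0])
    kappa = params.chemotactic_modulation

    def draw_run_durations(theta: np.ndarray) -> np.ndarray:
        mean = params.mean_run_duration * (1.0 + kappa * np.cos(theta - theta_g))
        mean = np.maximum(mean, dt)
        return np.maximum(rng.exponential(mean), dt)

    pos = rng.uniform([0, 0], params.arena, size=(n, 2))
    theta = rng.uniform(-np.pi, np.pi, size=n)
    running = np.ones(n, dtype=bool)
    timer = draw_run_durations(theta)
    alive = np.ones(n, dtype=bool)

    positions = np.empty((n_steps + 1, n, 2))
    states = np.empty((n_steps + 1, n), dtype=bool)
    alive_mask = np.empty((n_steps + 1, n), dtype=bool)
    rot_sd = np.sqrt(2.0 * params.rotational_diffusion * dt)

    for step in range(n_steps):
        positions[step] = pos
        states[step] = running
        alive_mask[step] = alive

        # displacement
        run_move = running & alive
        pos[run_move, 0] += params.speed * dt * np.cos(theta[run_move])
        pos[run_move, 1] += params.speed * dt * np.sin(theta[run_move])
        tum_move = (~running) & alive
        n_t = int(tum_move.sum())
        if n_t:
            phi = rng.uniform(-np.pi, np.pi, size=n_t)
            jit = TUMBLE_JITTER_FRACTION * params.speed * dt
            pos[tum_move, 0] += jit * np.cos(phi)
            pos[tum_move, 1] += jit * np.sin(phi)
        if rot_sd > 0:
            theta[run_move] += rot_sd * rng.standard_normal(int(run_move.sum()))

        if params.boundary == "reflect":
            _reflect(pos, theta, params.arena)
        else:  # absorb: freeze swimmers leaving the arena
            out = ((pos[:, 0] < 0) | (pos[:, 0] > params.arena[0]) |
                   (pos[:, 1] < 0) | (pos[:, 1] > params.arena[1]))
            newly = out & alive
            pos[newly] = np.clip(pos[newly], [0, 0], params.arena)
            alive &= ~out

        # state transitions (snapshot the state before modifying it)
        timer -= dt
        expired = (timer <= 0) & alive
        was_running = running.copy()
        run_end = expired & was_running
        if np.any(run_end):
            if params.mean_tumble_duration > 0:
                running[run_end] = False
                timer[run_end] = np.maximum(
                    rng.exponential(params.mean_tumble_duration, size=int(run_end.sum())),
                    dt)
            else:  # instantaneous reorientation, stay in run state
                kick = rng.normal(0.0, params.tumble_angle_spread, size=int(run_end.sum()))
                theta[run_end] = _wrap(theta[run_end] + kick)
                timer[run_end] = draw_run_durations(theta[run_end])
        tum_end = expired & ~was_running
        if np.any(tum_end):
            kick = rng.normal(0.0, params.tumble_angle_spread, size=int(tum_end.sum()))
            theta[tum_end] = _wrap(theta[tum_end] + kick)
            running[tum_end] = True
            timer[tum_end] = draw_run_durations(theta[tum_end])

    positions[n_steps] = pos
    states[n_steps] = running
    alive_mask[n_steps] = alive

    tracks = []
    frames = np.arange(n_steps + 1)
    fps = 1.0 / dt
    for i in range(n):
        keep = alive_mask[:, i]
        # absorbed swimmers end at the wall; keep the pre-absorption samples
        idx = frames[keep] if params.boundary == "absorb" else frames
        if len(idx) < 2:
            continue
        tracks.append(Track(track_id=i,
                            frames=idx,
                            positions=positions[idx, i],
                            frame_rate=fps,
                            source="synthetic",
                            states=states[idx, i]))
    return tracks


def _wrap(angle: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - angle, 2 * np.pi)


def ground_truth_drift(tracks: list[Track], gradient_axis=(0.0, 1.0)) -> float:
    """Brute-force ensemble drift: total axis displacement / total time, µm/s."""
    g = _unit(gradient_axis)
    disp = 0.0
    time = 0.0
    for tr in tracks:
        disp += float((tr.positions[-1] - tr.positions[0]) @ g)
        time += tr.duration
    return disp / time


def simulate_beads(params: BeadParams) -> list[Track]:
    """Independent 2-D Brownian paths; per-axis increments N(0, 2*D*dt)."""
    rng = np.random.default_rng(params.seed)
    n_steps = int(round(params.duration / params.dt))
    start = rng.uniform([0, 0], params.arena, size=(params.n_beads, 2))
    incr = rng.normal(0.0, np.sqrt(2.0 * params.diffusion_coefficient * params.dt),
                      size=(params.n_beads, n_steps, 2))
    paths = np.concatenate([start[:, None, :],
                            start[:, None, :] + np.cumsum(incr, axis=1)], axis=1)
    frames = np.arange(n_steps + 1)
    fps = 1.0 / params.dt
    return [Track(track_id=i, frames=frames, positions=paths[i],
                  frame_rate=fps, source="synthetic")
            for i in range(params.n_beads)]


def render_movie(tracks: list[Track], rp: RenderParams,
                 n_frames: int | None = None) -> tuple[ImageStack, pd.DataFrame]:
    """Render tracks as Gaussian spots on a noisy detector.

    Each frame is ``background + sum of isotropic Gaussian spots +
    N(0, noise_sd)``, quantized to uint16.  Returns the stack (carrying
    pixel_size and frame_rate) and a ground-truth table with columns
    (frame, track_id, x_um, y_um) for every rendered spot.
    """
    h, w = rp.image_shape
    if n_frames is None:
        n_frames = int(max(tr.frames[-1] for tr in tracks)) + 1 if tracks else 2
    n_frames = max(n_frames, 2)
    rng = np.random.default_rng(rp.seed)
    frames = np.zeros((n_frames, h, w))
    truth_rows = []
    radius = int(np.ceil(4 * rp.psf_sigma))

    # frame -> list of positions (px)
    for tr in tracks:
        for f, (x_um, y_um) in zip(tr.frames, tr.positions):
            if f >= n_frames:
                continue
            x_px, y_px = x_um / rp.pixel_size, y_um / rp.pixel_size
            if not (0 <= x_px < w and 0 <= y_px < h):
                if rp.out_of_view == "error":
                    raise ValueError(
                        f"track {tr.track_id} frame {f}: position outside field of view")
                continue
            _paint_spot(frames[f], x_px, y_px, rp.spot_amplitude, rp.psf_sigma, radius)
            truth_rows.append((int(f), tr.track_id, x_um, y_um))

    frames += rp.background
    if rp.noise_sd > 0:
        frames += rng.normal(0.0, rp.noise_sd, size=frames.shape)
    frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(truth_rows, columns=["frame", "track_id", "x_um", "y_um"])
    return ImageStack(frames, pixel_size=rp.pixel_size, frame_rate=rp.frame_rate), truth


def _paint_spot(img: np.ndarray, x_px: float, y_px: float,
                amplitude: float, sigma: float, radius: int) -> None:
    h, w = img.shape
    r0 = max(0, int(np.floor(y_px)) - radius)
    r1 = min(h, int(np.floor(y_px)) + radius + 1)
    c0 = max(0, int(np.floor(x_px)) - radius)
    c1 = min(w, int(np.floor(x_px)) + radius + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - y_px) ** 2 + (cc - x_px) ** 2) / (2.0 * sigma ** 2))


def synth_rotation_trace(op: OscillationParams,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Intensity trace: offset + A*sin(2*pi*f*t + phi) + Brownian background.

    The background is a random walk with increment variance
    ``2 * brownian_background_D * dt``, whose power spectrum falls as
    1/omega² — the signature of Brownian-motion-driven intensity
    fluctuations.  Phase is drawn from the seeded generator.
    """
    if rng is None:
        rng = np.random.default_rng(op.seed)
    t = np.arange(op.n_frames) / op.frame_rate
    phi = rng.uniform(0, 2 * np.pi)
    trace = op.offset + op.amplitude * np.sin(2 * np.pi * op.frequency * t + phi)
    if op.brownian_background_D > 0:
        incr = rng.normal(0.0, np.sqrt(2.0 * op.brownian_background_D / op.frame_rate),
                          size=op.n_frames - 1)
        trace[1:] += np.cumsum(incr)
    return trace


def synth_rotation_movie(op: OscillationParams,
                         image_shape: tuple[int, int] = (16, 16),
                         spots: tuple[tuple[float, float], ...] = ((4.0, 4.0),),
                         frequencies: tuple[float, ...] | None = None,
                         psf_sigma: float = 1.5,
                         base_amplitude_factor: float = 2.0,
                         noise_sd: float = 0.02,
                         pixel_size: float = 0.1) -> ImageStack:
    """Render oscillating Gaussian spots over a shared Brownian background.

    Each spot at (x_px, y_px) pulses as
    ``A0 + amplitude * sin(2*pi*f*t + phi)`` with ``A0 =
    base_amplitude_factor * amplitude`` (keeps intensity positive); the
    Brownian background from :func:`synth_rotation_trace` parameters is
    added uniformly to every pixel.  ``frequencies`` overrides
    ``op.frequency`` per spot (for multi-cell scenes).
    """
    rng = np.random.default_rng(op.seed)
    h, w = image_shape
    t = np.arange(op.n_frames) / op.frame_rate
    frames = np.full((op.n_frames, h, w), op.offset, dtype=float)

    if frequencies is None:
        frequencies = (op.frequency,) * len(spots)
    if len(frequencies) != len(spots):
        raise ValueError("frequencies must match spots")

    radius = int(np.ceil(4 * psf_sigma))
    a0 = base_amplitude_factor * op.amplitude
    for (x_px, y_px), f_hz in zip(spots, frequencies):
        phi = rng.uniform(0, 2 * np.pi)
        amp_t = a0 + op.amplitude * np.sin(2 * np.pi * f_hz * t + phi)
        for k in range(op.n_frames):
            _paint_spot(frames[k], x_px, y_px, amp_t[k], psf_sigma, radius)

    if op.brownian_background_D > 0:
        incr = rng.normal(0.0, np.sqrt(2.0 * op.brownian_background_D / op.frame_rate),
                          size=op.n_frames - 1)
        bg = np.concatenate([[0.0], np.cumsum(incr)])
        frames += bg[:, None, None]
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    return ImageStack(frames, pixel_size=pixel_size, frame_rate=op.frame_rate)
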