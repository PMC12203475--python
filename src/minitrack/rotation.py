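"""Flagellar rotation frequency from fluorescence movies via block PSDs.

Periodic intensity fluctuations caused by the rotating labeled flagellum
are read out as follows: the movie (56 fps, 128 frames by convention) is
tiled into non-overlapping 8x8-pixel blocks; each block's spatially
averaged intensity trace is Fourier transformed (mean removed) and its
power spectral density PSD(f) = |I~(f)|² computed on the positive
frequency grid f_k = k * frame_rate / n_frames.  Brownian motion of the
cell contributes a 1/omega² background, so the raw PSD is normalized by
that reference shape (divided by 1/omega², omega = 2*pi*f), flattening
the Brownian part while the rotation peak survives.  The dominant peak in a search band is refined
by fitting a parabola through the log-power of the peak bin and its two
neighbours; the vertex frequency is the rotation-frequency estimate.
Per cell, the block whose peak has the largest prominence wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import ImageStack

__all__ = [
    "PSDResult",
    "NoPeakError",
    "block_traces",
    "psd",
    "brownian_correct",
    "peak_frequency",
    "cell_rotation_frequency",
]

#: neighbour power below this fraction of the peak disables parabolic
#: refinement (an exact-bin tone would otherwise be shifted by float noise)
_REFINE_GUARD = 1e-9


class NoPeakError(ValueError):
    """Raised when no sufficiently prominent spectral peak exists."""


@dataclass
class PSDResult:
    """Power spectrum and refined peak for one cell."""

    frequencies: np.ndarray      # Hz, k * frame_rate / n_frames, k = 1..n/2
    raw_psd: np.ndarray
    corrected_psd: np.ndarray    # raw / omega²
    peak_frequency: float        # Hz
    peak_block: int | None = None
    prominence: float | None = None
    edge_peak: bool = False


def block_traces(stack: ImageStack, block: int = 8
                 ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Spatial-mean intensity trace of every non-overlapping block.

    Returns (traces, block_origins): traces is (n_blocks, T); origins
    are (row, col) of each block's top-left pixel.  Edge remainders that
    do not fill a whole block are dropped.
    """
    t, h, w = stack.frames.shape
    if h < block or w < block:
        raise ValueError(f"stack {h}x{w} smaller than one {block}x{block} block")
    nr, nc = h // block, w // block
    cropped = stack.frames[:, : nr * block, : nc * block].astype(float)
    blocked = cropped.reshape(t, nr, block, nc, block).mean(axis=(2, 4))
    traces = blocked.reshape(t, nr * nc).T
    origins = [(r * block, c * block) for r in range(nr) for c in range(nc)]
    return traces, origins


def psd(trace: np.ndarray, frame_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Raw power spectral density on the positive-frequency grid.

    The mean (DC) is removed, then PSD_k = |FFT(trace)_k|² for
    k = 1..n/2 at f_k = k * frame_rate / n.  Requires a power-of-two
    length.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n < 8 or n & (n - 1):
        raise ValueError(f"trace length must be a power of two >= 8, got {n}")
    spectrum = np.fft.rfft(trace - trace.mean())
    power = np.abs(spectrum[1:]) ** 2          # drop DC; includes Nyquist bin
    freqs = np.arange(1, n // 2 + 1) * frame_rate / n
    return freqs, power


def brownian_correct(freqs: np.ndarray, power: np.ndarray) -> np.ndarray:
    """Normalize out the Brownian background: divide each bin by its
    1/omega² reference shape (equivalently, multiply by omega² =
    (2*pi*f)²).

    A cell jiggling under Brownian motion contributes intensity
    fluctuations whose power spectrum falls as 1/omega²; dividing the
    raw PSD by that reference whitens the background to flat, so the
    flagellar-rotation peak stands out uniformly across the band.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("brownian_correct requires the DC bin to be excluded")
    return np.asarray(power, dtype=float) * (2 * np.pi * freqs) ** 2


def peak_frequency(freqs: np.ndarray,
                   power: np.ndarray,
                   band: tuple[float, float] | None = None,
                   prominence: float = 20.0
                   ) -> tuple[float, float, bool]:
    """Refined frequency of the dominant spectral peak in a band.

    Locates the maximal bin within ``band`` (default 2 Hz to 0.9x
    Nyquist, excluding the low-frequency 1/omega² residue), then fits a
    parabola through log-power at the peak bin and its two neighbours
    and returns the vertex frequency.  Refinement never moves the
    estimate more than half a bin; it is skipped when the neighbours
    carry essentially no power (bin-exact tone).

    Returns (frequency_hz, prominence_ratio, on_band_edge).  Raises
    :class:`NoPeakError` when max/median power in the band is below
    ``prominence``.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    nyquist = freqs[-1]
    if band is None:
        band = (2.0, 0.9 * nyquist)
    in_band = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    if len(in_band) < 3:
        raise ValueError("search band must contain at least 3 bins")

    band_power = power[in_band]
    med = np.median(band_power)
    pmax = band_power.max()
    ratio = np.inf if med == 0 else pmax / med
    if pmax == 0 or ratio < prominence:
        raise NoPeakError(
            f"no prominent peak: max/median = {ratio:.2f} < {prominence}")

    k = in_band[int(np.argmax(band_power))]
    edge = k == in_band[0] or k == in_band[-1]
    f_hat = freqs[k]
    if 0 < k < len(power) - 1:
        left, centre, right = power[k - 1], power[k], power[k + 1]
        if min(left, right) > _REFINE_GUARD * centre:
            l, c, r = np.log(left), np.log(centre), np.log(right)
            denom = l - 2 * c + r
            if denom < 0:
                delta = 0.5 * (l - r) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
                df = freqs[1] - freqs[0]
                f_hat = freqs[k] + delta * df
    return float(f_hat), float(ratio), bool(edge)


def cell_rotation_frequency(stack: ImageStack,
                            roi: tuple[int, int, int, int] | None = None,
                            block: int = 8,
                            band: tuple[float, float] | None = None,
                            prominence: float = 20.0) -> PSDResult:
    """End-to-end rotation frequency for one cell.

    ``roi`` is (row0, row1, col0, col1) in pixels (half-open), typically
    the manually selected area around one swimming cell; None uses the
    whole frame.  Each block trace yields a Brownian-corrected PSD; the
    cell's value is the refined peak of the block with maximal peak
    prominence.  Raises :class:`NoPeakError` when no block shows a
    prominent peak (background-only region).
    """
    if roi is not None:
        r0, r1, c0, c1 = roi
        t, h, w = stack.frames.shape
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"roi {roi} outside stack of shape {(h, w)}")
        sub = ImageStack(stack.frames[:, r0:r1, c0:c1],
                         pixel_size=stack.pixel_size, frame_rate=stack.frame_rate)
    else:
        sub = stack

    traces, _ = block_traces(sub, block=block)
    best: PSDResult | None = None
    for bi, trace in enumerate(traces):
        freqs, raw = psd(trace, sub.frame_rate)
        corrected = brownian_correct(freqs, raw)
        try:
            f_hat, ratio, edge = peak_frequency(freqs, corrected, band=band,
                                                prominence=prominence)
        except NoPeakError:
            continue
        if best is None or ratio > best.prominence:
            best = PSDResult(frequencies=freqs, raw_psd=raw,
                             corrected_psd=corrected, peak_frequency=f_hat,
                             peak_block=bi, prominence=ratio, edge_peak=edge)
    if best is None:
        raise NoPeakError("no block in the ROI shows a prominent spectral peak")
    return best
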