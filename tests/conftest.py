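import numpy as np
import pytest

import minitrack as mt
from minitrack.tracking import Track


@pytest.fixture(scope="session")
def null_ensemble():
    """Unbiased (kappa=0) run-and-tumble population, 200 swimmers x 30 s."""
    return mt.simulate_run_tumble(
        mt.SwimmerParams(n_swimmers=200, duration=30.0, seed=11))


@pytest.fixture(scope="session")
def biased_ensemble():
    """Chemotactic (kappa=0.5) population, 200 swimmers x 60 s."""
    return mt.simulate_run_tumble(
        mt.SwimmerParams(n_swimmers=200, duration=60.0,
                         chemotactic_modulation=0.5, seed=12))


@pytest.fixture(scope="session")
def bead_ensemble():
    """500 Brownian beads at D = 0.35 µm²/s, 200 frames at 50 fps."""
    return mt.simulate_beads(
        mt.BeadParams(diffusion_coefficient=0.35, n_beads=500,
                      duration=4.0, seed=13))


def ground_truth_runs(tracks, min_run_frames=5, gradient_axis=(0.0, 1.0)):
    """Build RunSegments directly from the generator's state labels.

    Independent of segment_runs: a plain scan over the stored boolean
    run mask, censored intervals at the track ends included.
    """
    from minitrack.runtumble import _make_segment
    runs = []
    for tr in tracks:
        mask = tr.states
        n = len(tr)
        i = 0
        while i < n:
            j = i
            while j + 1 < n and mask[j + 1] == mask[i]:
                j += 1
            if mask[i] and j - i >= min_run_frames:
                runs.append(_make_segment(tr, i, j, gradient_axis))
            i = j + 1
    return runs


def make_track(positions, frame_rate=50.0, track_id=0):
    positions = np.asarray(positions, dtype=float)
    return Track(track_id=track_id, frames=np.arange(len(positions)),
                 positions=positions, frame_rate=frame_rate, source="synthetic")


@pytest.fixture
def straight_track():
    """60 frames at exactly 10 µm/s along +y at 50 fps."""
    t = np.arange(60) / 50.0
    pos = np.column_stack([np.zeros_like(t), 10.0 * t])
    return make_track(pos)
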