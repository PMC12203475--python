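# minitrack

Trajectory and image analysis for motile bacterial **minicells** —
submicrometre, chromosome-free compartments budded from *min*-mutant
*E. coli* that swim when flagellated — and the minibot biohybrids made
by attaching cargo beads to them. The package is for experimentalists
quantifying microswimmer motility and chemotaxis from time-lapse
microscopy: it turns movies (or pre-tracked trajectory tables) into
run/tumble statistics, chemotactic drift, motile fractions, flagellar
rotation frequencies and accumulation counts, and ships a
ground-truthed synthetic data generator so every stage is testable
without raw microscopy.

## What it computes

**Chemotaxis.** Trajectories are segmented into runs and tumbles; each
run *j* gets a direction angle relative to the attractant gradient axis
*g*,

    α_j = arccos( g·d_j / |d_j| ) ∈ [0, π],

with runs classed *up* the gradient when α < π/4 and *down* when
3π/4 < α < π. Runs shorter than 5 frames (0.1 s at 50 fps) are removed.
The population drift velocity is the duration-weighted mean of
per-trajectory end-to-end velocities,

    V_X = Σ_i V_X,i · T_i / Σ_i T_i,   V_X,i = (X_end,i − X_start,i)/T_i,

which equals total axis displacement over total tracked time. With the
population swimming speed *V* (mean instantaneous speed within runs),
the chemotactic **bias** is V_X/V and the **efficiency** is V_X/V².

**Tracking & classification.** Sub-pixel spot detection, gated greedy
nearest-neighbour linking, and MSD-based diffusion estimation
(D = slope/4 over lags 1–10). Tracks with D above a threshold —
default 5× the Stokes–Einstein D of a 1.4 µm bead at 22.5 °C — are
classed actively propelled; the motile fraction follows.

**Flagellar rotation.** Fluorescence movies (56 fps, 128 frames) are
tiled into 8×8-pixel blocks; each block's mean-intensity trace yields a
power spectral density, whitened against the 1/ω² Brownian background
and scanned for its dominant peak, refined by a 3-point log-parabola.
The most prominent block gives the cell's rotation frequency.

**Synthetic ground truth.** Run-and-tumble swimmers (exponential run
durations, mean modulated by `1 + κ·cos α` along the gradient),
Brownian beads of known D, rendered Gaussian-spot movies with
configurable SNR, and oscillating intensity traces on Brownian
backgrounds — all seeded and bit-reproducible.

## Worked example

```python
import minitrack as mt

params = mt.SwimmerParams(n_swimmers=300, duration=60.0,
                          chemotactic_modulation=0.5, seed=7)
tracks = mt.simulate_run_tumble(params)

runs = []
for tr in tracks:
    runs += mt.segment_runs(tr, gradient_axis=(0.0, 1.0))[0]

s = mt.chemotaxis_summary(tracks, runs, gradient_axis=(0.0, 1.0))
print(f"V_X  = {s.V_X:.3f} um/s")
print(f"V    = {s.V:.2f} um/s")
print(f"bias = {s.bias:.4f}")
print(f"runs up/down: {s.n_runs_up}/{s.n_runs_down}, "
      f"mean {s.mean_run_up:.3f}/{s.mean_run_down:.3f} s")

op = mt.OscillationParams(frequency=15.5, seed=3)
res = mt.cell_rotation_frequency(mt.synth_rotation_movie(op))
print(f"rotation: {res.peak_frequency:.2f} Hz")
```

prints

```
V_X  = 2.333 um/s
V    = 14.99 um/s
bias = 0.1556
runs up/down: 3402/3180, mean 1.480/0.708 s
rotation: 15.45 Hz
```

The chemotactic population (κ = 0.5) drifts up the gradient at
2.3 µm/s while swimming at its generative 15 µm/s (bias 0.16); runs
pointing up the gradient last about twice as long as runs pointing down
(1.48 s vs 0.71 s) — the run-extension signature of chemotaxis. The
15.5 Hz oscillation planted in the movie is recovered to within a
twentieth of a spectral bin.

The same stages are available from the shell:

```sh
minitrack simulate swimmers --seed 1 --out out/
minitrack segment --tracks out/swimmers.csv --out out/runs.csv
minitrack chemotaxis --tracks out/swimmers.csv --runs out/runs.csv --out out/summary.json
```

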