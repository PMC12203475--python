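# Methods

`minitrack` quantifies the swimming behaviour of flagellated bacterial
minicells — submicrometre, chromosome-free compartments budded from
*min*-mutant *E. coli* — and of the "minibot" biohybrids made by
attaching cargo beads to them. It implements the full measurement chain:
spot detection and trajectory linking from time-lapse movies,
run/tumble segmentation, population chemotaxis statistics, diffusion-
threshold classification of actively transported cargo, PSD-based
flagellar rotation frequency, and accumulation counting. Every stage is
validated against a synthetic generator with known ground truth.

## The run-and-tumble model and the synthetic generator

Swimmers alternate **runs** — ballistic motion at constant speed `v`
with rotational diffusion of the heading, `dθ = √(2 D_rot dt)·ξ` — and
**tumbles** — near-stationary jitter followed by a random reorientation.
Defaults (chosen to match the acquisition and organism being emulated):

| parameter | default | unit | rationale |
|---|---|---|---|
| `speed` | 15 | µm/s | typical motile-minicell swimming speed scale |
| `mean_run_duration` | 1.0 | s | run/tumble alternation on the ~1 s scale |
| `mean_tumble_duration` | 0.1 | s | brief reorientation events |
| `rotational_diffusion` | 0.1 | rad²/s | gentle run curvature |
| `tumble_angle_spread` | 1.2 | rad | std of the Gaussian reorientation kick (~69°, the classic enteric-bacteria tumble-angle scale) |
| `dt` | 0.02 | s | 50 fps phase-contrast sampling |
| arena | 2000×2000 | µm | reflecting walls keep density uniform |

Chemotaxis is abstracted as heading-dependent run-length modulation:
run durations are exponential with mean
`mean_run_duration·(1 + κ·cos α)`, where `α` is the angle between the
heading at run start and the gradient axis and `κ ≥ 0` is a
dimensionless modulation depth. This is the minimal generative
mechanism that produces the "runs extended up the gradient" signature;
it involves no explicit concentration field, receptor kinetics or
adaptation dynamics. Draws are truncated below at `dt` so every run is
at least one frame.

Tumbles are rendered as zero-mean jitter at 10% of run speed (so
speed-based segmentation faces a realistic, not infinite, contrast);
the reorientation angle is Gaussian with the spread above, wrapped to
(−π, π]. The true tumble-angle distribution of minicells is unknown;
the Gaussian is a declared stand-in, not an inference. When
`mean_tumble_duration = 0` the reorientation is instantaneous and no
frame is ever labelled tumble.

What the generator does **not** emulate: localization noise on
trajectory positions (tracks are exact unless rendered through the
movie pipeline), hydrodynamic wall interactions, speed variability
across individuals, 3-D motion, photobleaching. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every artefact of real microscopy; the rendering path
(Gaussian spots + additive Gaussian noise, not Poisson shot noise)
covers the detection-noise axis at configurable SNR.

Brownian beads are free 2-D walkers with per-axis increment variance
`2·D·dt`. The default `D = 0.35 µm²/s` is the Stokes–Einstein value for
the 1.4 µm streptavidin-coated cargo beads in water at the 22.5 °C
assay temperature (0.33 µm²/s, rounded).

## Segmentation and per-run kinematics

The published analyses in this field rely on external tracker code
whose run/tumble criteria are not public, so this package declares its
own two-criterion rule: a step is a tumble when the smoothed
instantaneous speed falls below `speed_drop_fraction` (default 0.5) of
the track's median smoothed speed, **or** when the smoothed turning
rate exceeds `turn_rate_threshold` (default 25 rad/s). Speeds and
headings are smoothed with a 3-frame moving average. During runs the
position-derived turning rate has standard deviation
`√(2 D_rot/dt) ≈ 3 rad/s` at the defaults, so 25 rad/s is a >5σ gate
that fires essentially only on genuine reorientations and on Brownian
jitter (whose frame-to-frame headings are nearly uniform, giving
turning rates of order 100 rad/s). Maximal tumble-free intervals become
run segments; **runs spanning fewer than 5 frames (0.1 s at 50 fps) are
removed** before duration statistics (strict "shorter than": a 5-frame
run survives).

Each run carries the direction angle

    α = arccos( g·d / |d| ) ∈ [0, π],

with `d` the end-to-end displacement and `g` the unit gradient axis.
The gradient axis is explicit configuration, defaulting to ŷ so that
`α = arccos(Δy/√(Δx²+Δy²))`. Runs are classed *up* when `α < π/4` and
*down* when `3π/4 < α < π`; both inequalities are strict, and the
boundary cones are "neither" (contributing to speed and drift but not
to the per-direction duration means).

## Chemotaxis statistics

Per-trajectory drift is the gradient-axis component of
`(end − start)/T_i` with `T_i` the whole-trajectory wall-clock duration
(tumbles and gap-filled frames included). The population drift is the
duration-weighted mean

    V_X = Σ_i V_X,i·T_i / Σ_i T_i = Σ_i Δx_i / Σ_i T_i,

an algebraic identity this package asserts to machine precision. The
population swimming speed `V` is the mean instantaneous speed pooled
over frames inside classified runs (run-conditioned, not whole-track).
Chemotactic bias is `V_X/V`; chemotactic efficiency is `V_X/V²` (s/µm).
An empty direction class reports its mean run duration as missing
(`None`), never zero.

## Diffusion classification

The time-averaged MSD over lags 1–10 is fit by least squares; `D` is
slope/4 and the intercept absorbs localization noise. Ballistic swimmers
have MSD ≈ v²τ² over these short lags, giving apparent `D` of tens of
µm²/s versus ~0.35 for the beads, so a threshold at 5× the theoretical
bead `D` (≈1.6 µm²/s, overridable) separates the populations with a wide
margin. The motile fraction is the proportion of tracks above threshold.

## Spot detection and linking

Detection: Gaussian smoothing at `min_sigma`, local maxima above
`median + threshold`, sub-pixel refinement by background-subtracted
intensity-weighted centroid in a window of radius `2·max_sigma` (wide
enough for >95% of the spot mass, narrow enough not to swallow
neighbours ≥8 px away), deduplication within 1 px. Linking: gated
greedy nearest-neighbour assignment in order of increasing distance,
gate `max_disp·(gap+1)`, each detection used at most once; gaps up to
`max_gap` frames are bridged with linearly interpolated positions
flagged `gap_filled`. These are declared, testable stand-ins for the
unpublished tracker the original analyses used; Kalman or
multiple-hypothesis linking is out of scope.

## Flagellar rotation frequency

Movies (56 fps, 128 frames) are tiled into non-overlapping 8×8-pixel
blocks; each block's spatial-mean trace is mean-subtracted and
transformed with a real FFT, giving the PSD on the grid
`f_k = k·56/128` (bin width 0.4375 Hz). Averaging before transforming
equals transforming per pixel and averaging (linearity; unit-tested).

**Brownian whitening.** Brownian motion of the cell drives intensity
fluctuations with a 1/ω² power spectrum. The raw PSD is therefore
normalized by that reference shape — divided by 1/ω², i.e. multiplied
by ω² — which flattens the Brownian background so the rotation peak
stands out uniformly across the band. On sampled data the walk's true
spectrum is ∝ 1/(4·sin²(πf/f_s)), which departs from 1/ω² above ~half
Nyquist; the whitened background is flat (|log-log slope| ≲ 0.1) over
the 2–14 Hz mid-band and tilts gently toward Nyquist. The peak search
band (default 2 Hz to 0.9×Nyquist) excludes the lowest bins where any
residual low-frequency power concentrates.

**Peak refinement.** The maximal bin in the band and its two neighbours
are fit with a parabola in log power; the vertex frequency is the
estimate. Log power makes the peak symmetric; the vertex is clamped to
±half a bin, and refinement is skipped when both neighbours hold
< 1e−9 of the peak power (a bin-exact tone would otherwise be displaced
by floating-point noise). A spectrum whose band max/median ratio is
below 20 raises a no-peak error — a whitened Brownian-only periodogram
reaches ratios around 6–12, so 20 rejects background while any
oscillation at amplitude-to-background ratios ≥ 3 exceeds it by orders
of magnitude. Per cell, the block with the most prominent peak wins;
cross-block aggregation is a declared choice, as is the 3-point
log-parabola.

The oscillation generator's default Brownian background
(`D = 0.05 intensity²/s` at amplitude 1, 56 fps, 128 frames) puts the
RMS background fluctuation near amplitude/3 — i.e. SNR ≈ 3, from the
closed form `var ≈ D·N·dt` for the window-averaged walk variance.

## Problem sizes and numerical choices

The validation suite uses 500-swimmer × 60 s ensembles at 50 fps for
chemotaxis (null and κ ∈ {0.25, 0.5}), 500 beads × 200 frames for
diffusion recovery, 100 oscillation traces for rotation RMSE, and
20-spot rendered frames at SNR 10 for detection — sizes at which the
estimators' sampling error is well below the tolerances being checked
while the whole suite runs in well under a minute. Degenerate inputs
are errors with named fields (invalid parameters), explicit exceptions
(too-short tracks for MSD, zero displacement for α, flat spectra), or
documented empties (blank frames detect nothing; tracks shorter than
`2·min_run_frames` are skipped with a warning).

## Known limitations

- Frame labels at run/tumble boundaries are ambiguous by ±1–2 frames
  (smoothing); segmentation agreement with ground truth is ~93–97%, not
  100%, and short-run filtering discards genuine sub-0.1 s runs.
- The drift estimator's `T_i` includes tumbles and gap-filled frames;
  drift magnitudes are therefore slightly diluted relative to a
  run-only definition.
- The greedy linker can swap identities when two particles pass within
  the gate of each other in the same frame (<1% of links at the tested
  densities).
- Rotation estimates assume a single dominant oscillation per block;
  two cells in one 8×8 block are not separable.
- `κ` is a phenomenological dial, not a receptor-level model: recovered
  drift validates the estimator chain, not chemotactic signalling.
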