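# Methods

This note documents the models, parameters and numerical choices behind
`focitrack`, and what the synthetic-data validation does and does not show.

## Synthetic time-lapse model

The generator (`focitrack.simulate`) emulates a confocal acquisition of one
nucleus expressing a GFP-tagged DSB marker, imaged every 20 min:

- **Geometry.** The nucleus is an ellipse (default semi-axes 9.0 × 7.0 µm at
  0.1 µm/px in a 256×256 field) with strictly positive nucleoplasm intensity
  (default 40 on a 0–255 scale) over a dimmer exterior (8), so the per-frame
  nuclear mean/SD statistics of the adaptive threshold are always defined.
  Optional whole-nucleus drift (px/frame) and rotation (deg/frame) emulate
  cell movement; ground-truth positions are recorded in image coordinates,
  i.e. after drift.
- **Foci.** Each focus is an isotropic 2D Gaussian of width σ = 2 px rendered
  at its true position. Foci are born as a Poisson process (default
  0.03/frame), die per-frame with Bernoulli probability (0.02), and move by
  2D Brownian motion with per-axis step variance 2·D·Δt (default
  D = 0.005 µm²/min), optionally reflected at a confinement disc. An optional
  minimum center separation at placement supports low-density benchmarks.
- **Photometry.** Amplitudes grow by a per-frame fraction (default 1%),
  the whole frame decays by a global bleaching factor (0.5 %/frame), and
  noise is Poisson shot noise on the rendered signal plus additive Gaussian
  read noise — the standard fluorescence detector model; both components can
  be set to zero for exact tests. Frames are clipped to [0, 255] and kept in
  float32, so no quantization interferes with monotonicity tests.
- **Determinism.** All randomness flows from one `numpy` Generator seeded by
  the config; identical config ⇒ bit-identical stack and truth.

The defaults simulate in the projected 2D plane directly (the analysis
operates on maximum-intensity projections, so a full 3D render would add
nothing the pipeline could see). What the generator does **not** emulate:
radiation-track geometry or dose–response, spatially varying background,
nuclear deformation, focus shape irregularity, and camera artifacts beyond
Poisson+Gaussian noise. Passing ground-truth recovery on these images
therefore validates the *algorithms*, not instrument-specific performance on
real data.

The fixed-cell generator lays nuclei on a grid (0.04 µm/px, emulating a
higher-resolution acquisition), renders channel-A foci (σ = 6 px) with an
enforced minimum separation so the segmentation task is well posed, draws a
nested channel-B count per A focus from a user distribution, and places B
foci (σ = 2 px) within 0.6·σ_A of the parent center — comfortably inside the
thresholded A footprint (measured radius ≈ 0.8·σ_A), honoring the contract
that nested foci lie strictly inside their parent. An EdU channel encodes
per-nucleus S-phase status (bright ≈ 150 vs dim ≈ 25).

## Segmentation

- **Nuclei**: three-class multi-Otsu, lowest cut. With bright sub-nuclear
  foci present, two-class Otsu can land between nucleoplasm and foci and
  segment the foci instead of the nucleus; the three-class variant separates
  background / nucleoplasm / foci and keeps the outer boundary. Images with
  fewer than three distinguishable classes fall back to two-class Otsu.
  Holes are filled, border-touching components and components under 200 px
  are discarded (both configurable).
- **Stabilization**: rigid-body registration of every frame to frame 0.
  Rotation is estimated from the angular shift of the polar-transformed,
  log-scaled FFT magnitude (DC neighbourhood suppressed; 720 angular bins
  with 20× subpixel correlation ⇒ ~0.025° resolution, validated to < 0.5°
  error at 5° rotations), translation by phase cross-correlation after
  de-rotation. Out-of-frame pixels are filled with the frame median.
- **Adaptive threshold**: factor = (L − mean₀)/sd₀ with the *sample* SD
  (n−1 denominator); threshold_t = mean_t + factor·sd_t, factor constant per
  cell. Statistics are computed on the raw frames; the σ = 1 px Gaussian
  blur enters only as the surface on which watershed markers are detected.
  The upper threshold is 255; higher-bit-depth input is linearly rescaled to
  the 8-bit range and the scale recorded in the run manifest.
- **Watershed**: touching foci are split by watershed seeded at local maxima
  of the σ-smoothed intensity (minimum peak distance 2 px). The classic
  binary distance-transform watershed is available (`split_method=
  "distance"`) but fails to split overlapping diffraction-limited spots when
  the merged mask has no waist — two σ = 2 px Gaussians 5 px apart merge into
  a convex blob at generous thresholds — whereas the intensity surface always
  carries both peaks. Blobs under 4 px are dropped (configurable, 0 for
  exact-oracle tests).
- **Measurement**: area = pixel count × pixel_size²; mean intensity without
  background subtraction (whether the reference protocol subtracts
  background is unstated; none is applied here); center of mass is the
  intensity-weighted centroid (geometric centroid optional). Pixel (0, 0)
  has its center at (0, 0) µm.

## Tracking

Candidate links are pairs of consecutive-frame foci with COM distance
strictly below 0.7 µm (`inclusive=True` switches to ≤). Assignment is greedy
by ascending distance, ties broken by ascending labels, so the linker is
deterministic and each focus continues at most one track. A focus with ≥ 2
in-range candidates ahead records a split; ≥ 2 foci sharing one candidate
record a merge. The continuing track follows the nearest partner; other
branches start or end their own tracks carrying `split_from`/`merged_into`
annotations. Tracks are gap-free by construction, may start or end at any
frame, and duration = (n − 1)·Δt, so single-frame foci have duration 0 and
are kept out of the duration groups. No gap closing, no motion-model
prediction, no globally optimal assignment — the linker is intentionally a
distance-threshold device whose behavior is easy to audit against an
exhaustive oracle.

Duration groups are closed intervals 20–80, 100–160, 180–240, 260–320,
340–400 min plus overflow; durations are multiples of Δt, and a value
falling between two printed edges (impossible for multiples of 20) is
assigned to the group whose upper edge is next above it.

## Mobility analysis

MSD is time-averaged over all ordered in-track pairs (overlapping windows,
the common single-particle-tracking default). Ensemble curves average
per-track MSDs per lag, unweighted by track length, with SEM across tracks,
truncated at the last lag supported by ≥ 3 tracks. The diffusion fit is
unweighted least squares through the origin on the first four nonzero lags
(lag 0 is identically zero and excluded as a data point); D = slope/4 from
MSD = 2·d·D·t with d = 2.

Curvature classification fits the through-origin line against a
single-exponential plateau c·(1 − e^(−t/τ)). Because the plateau nests the
line (τ → ∞), residuals alone always prefer it; the curve is labelled
saturating only when the plateau halves the squared-residual sum **and** the
fitted τ lies inside the observed lag range — otherwise the bend is
extrapolation, not evidence of confinement. Curves with fewer than 6 nonzero
lags are indeterminate.

## Distributions

Kernel density estimates use a Gaussian kernel whose bandwidth is the kernel
SD in data units (defaults 6 for per-focus mean intensity, 0.3 µm² for area,
220 for total signal). The unit-area density is rescaled to the area of the
source histogram (or to a shared target area when two conditions are
compared after equal-area scaling), and a peak-normalization factor computed
on the first-time-point histogram (tallest bar ⇒ 1) is reused for later time
points of the same quantity. Per-frame time series report mean ± SEM of
intensity, area and total per focus; frames without foci report missing
values, never zero.

## Colocalization

Per-nucleus automatic (Otsu) thresholds segment both channels, floored at
mean + 3·SD of the nuclear pixels so that nuclei containing no foci yield no
labels instead of noise speckle. B-in-A assignment is by containment of the
B center of mass in the A label mask — unambiguous on a label partition, so
each B focus counts for at most one A focus. EdU-positive nuclei are
selected by Otsu over per-nucleus mean EdU intensities; when the means span
less than 25% of their median (one population) or only one nucleus exists,
the automatic threshold is undefined and a configured absolute cutoff (or,
with a warning, no selection) is used instead.

## Pipeline and reproducibility

The analysis contains no random step: given a stack and a config, reruns are
byte-identical, which the test suite asserts on the CSV outputs. All tables
name their units in the column headers (µm, µm², min). Problem sizes used in
the validation suite — 10–20-frame stacks of 160–200 px, 300–500 simulated
tracks, 200 nuclei / 1000 A foci for colocalization — were chosen so each
statistical check has comfortable Monte-Carlo margin while the whole suite
runs in well under a minute per module.

## Known limitations

- Nucleus identity is fixed at frame 0; touching or dividing nuclei are not
  tracked.
- The linker has no gap closing, so a single missed detection splits a track
  in two — matching the gap-free track definition, but worth remembering
  when interpreting duration histograms.
- Apparent D from noisy images is biased upward by localization error (the
  MSD offset), visible when comparing image-based fits with fits on true
  trajectories.
- The EdU-selection degeneracy rule (25% relative spread) is a heuristic;
  fields mixing nearly identical populations should set an explicit cutoff.
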