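# Methods

This note documents the models, numerical choices and limitations behind
`droprheo`, in the order the pipeline runs.

## Synthetic scenes

Every generator produces 2D grayscale time-lapse stacks through one optics
model and returns its exact ground truth, so each downstream measurement can
be validated against known parameters.

**Optics.** Droplets are rendered as flat-top ellipses on a 4× supersampled
grid and block-averaged down, giving sub-pixel edge placement (diameter
recovery at the 1–2% level is meaningful rather than quantization-limited).
The ideal projection is blurred with a Gaussian point-spread approximation
(`blur_sigma`, px), offset by a uniform `background_level`, converted to
expected photon counts via `photon_scale` (expected photons per intensity
unit), Poisson-sampled, and optionally given Gaussian read noise.
`photon_scale_for_snr(snr)` inverts this model so scenes can be specified by
peak signal-to-noise ratio. Overlapping droplets take the maximum intensity:
a uniform dense phase does not double its density where projections overlap.
Differential-interference-contrast imaging is not modelled; all scenes are
fluorescence-like, which carries every quantitative readout the pipeline
measures.

**Fusion.** The generative model for coalescence is the empirical
exponential shape relaxation itself, not a hydrodynamic neck-growth
simulation: after onset the droplet is a prolate spheroid with projected
aspect ratio `AR(t) = 1 + (AR_init − 1)·e^(−t/τ)` and `τ = (η/γ)(d₁+d₂)`.
The in-plane axes follow from exact volume conservation,
`b = (d_final³/AR)^(1/3)`, `a = AR·b`, so `a·b² = d₁³ + d₂³` holds to
machine precision at every frame; the droplet is assumed to rest with its
long axis in the imaging plane, which is how fusions appear in practice.
The initial aspect ratio uses the touching-spheres bounding geometry
`AR_init = (d₁+d₂)/max(d₁,d₂)`. Pre-onset frames show the two circles
separated by a 3-pixel gap so segmentation resolves the pair; movies must
span at least 3τ after onset so the decay is observable (enforced).

**Brownian ensembles.** Per-frame displacements are independent
`N(0, 2·D·Δt)` per axis; a finite `confinement_radius` reflects excursions
radially about each droplet's starting anchor, otherwise droplets reflect at
the arena walls. Starting positions sit on a grid inset from the walls by at
least 20% of the arena so wall reflections stay rare over a typical movie.
Exact trajectories are returned at full precision.

**FRAP.** The droplet interior is a disk lattice at the pixel spacing
(required ≤ radius/10) carrying two species: a mobile fraction diffusing at
`D_in` under an explicit 5-point scheme whose neighbour exchange is
restricted to in-disk sites — a no-flux boundary that conserves total mass
exactly — and a static immobile fraction. The scheme is automatically
sub-stepped so `D·dt/dx² ≤ 0.25` always holds (stability is never traded for
silent inaccuracy). Bleaching multiplies both species inside the ROI by
`(1 − bleach_depth)` at the bleach frame; the bleach spot is a hard-edged
disk (the in-scope profile; the generator accepts any ROI geometry). With
`exchange_rate > 0` the mobile species relaxes toward the unbleached
dilute-phase reservoir, the mechanism behind whole-droplet recovery; the
default is a closed droplet (no exchange), matching passivated-glass
conditions where exchange is negligible.

**Dissolution and grids.** Fluid droplets shrink linearly to nothing within
a few frames of the treatment frame (chelation of the divalent cation that
sustains them); photocrosslinked droplets persist unchanged; a
`persist_fraction` produces mixed fields. Condition grids render
`min_count`-plus droplets in "present" cells and background (optionally
sub-diameter speckle) in "absent" cells.

All generators are bit-reproducible given a seed; every stack written to
disk carries its calibration, quantization scale and seed in a sidecar.

## Segmentation and tracking

Frames are thresholded globally (Otsu by default; a fixed absolute threshold
is available for low-contrast data), hole-filled, and labelled with
8-connectivity; regions below a minimum equivalent diameter are discarded
and border-touching regions are flagged and excluded from shape statistics.
Two guards reject degenerate thresholdings: a foreground fraction above 35%
(droplet fields analysed here never cover that much area) and an Otsu class
separation below 4 pooled within-class standard deviations — thresholding a
unimodal noise histogram lands near 2.7 on that statistic regardless of the
noise scale, while genuine droplet/background bimodality sits well above it.
The aspect ratio is taken from the ellipse with the region's second central
moments (rotation-invariant), not a bounding box. Coordinates are 0-based
`(row, col)` pixels internally; all reported centroids are μm with
`x = col·pixel_size`, `y = row·pixel_size`.

Linking minimises total centroid displacement per frame pair (optimal
bipartite assignment) with a hard gate of `max_displacement_um` per frame of
gap; tracks coast through up to `memory_frames` missed detections.

Fusion events are detected by two complementary rules: (i) two tracks end at
frame f−1 within `(r₁+r₂) + proximity_tol` of each other and a new track at
f lies in their joint bounding box with area within 25% of their sum;
(ii) one track ends next to a surviving track whose area jumps by the ended
track's area — the case where the merged droplet's centroid lands close to
the larger parent and the linker keeps that parent's identity. Rule (ii) is
essential for unequal pairs: with diameters drawn from U(2,6) μm the
parent-to-product centroid jump is often smaller than any reasonable linking
gate. Candidates sharing a parent keep the geometrically closest pair.
Pre-fusion diameters average the 3 frames before onset (configurable via
`k_pre_frames`).

## Fusion rheology

Each event's AR series is fit by nonlinear least squares to
`AR(t) = 1 + (AR_init − 1)·e^(−t/τ)` anchored at the first sample (uniform
time shifts leave τ unchanged), with τ initialised from the first crossing
of `(AR_init−1)/e` and bounds τ > 0, AR_init ≥ 1. AR values below 1 from
measurement noise are clipped to 1 (values below 0.98 are rejected as a
domain violation); a flat series near AR = 1 is reported as non-converged
rather than fit. Events with non-converged fits or r² < 0.8 (configurable)
are excluded from the capillary regression and counted.

The inverse capillary velocity is the slope of an ordinary least-squares fit
of τ against `l = d₁ + d₂` with a **free intercept**: the intercept absorbs
detection-onset latency while the slope is the reported material property.
The fit is unweighted — per-event fit uncertainties are not propagated into
the regression. The length scale is the sum of pre-fusion diameters (the
quantity regressed in coalescence assays), and the volume ratio
`d_post³/(d₁³+d₂³)` is reported per event as an internal control.

## Mobility analysis

Tracks are cut into overlapping fixed-length windows (default length 20,
stride 1); windows crossing detection gaps are dropped. This reproduces the
many-trajectories-per-droplet accounting common in condensate tracking
studies, at the cost that the SE over windows understates their correlation
— a deliberate, documented convention rather than a statistical claim. The
MSD is time-averaged within each window and ensemble-averaged across
windows; the fit `MSD = 4·D·lag + offset` over the first lags (default 5)
is weighted by 1/SE² and keeps a free intercept, which absorbs the
`≈ 4σ_loc²` localization-noise offset without biasing the slope. The
anomalous exponent α is the unweighted log-log slope over the same lags, and
is undefined (NaN) when any MSD in range is non-positive.

Classification: immobile when `D < 10⁻³ μm²/s`, otherwise diffusive when α
lies in [0.9, 1.1], else subdiffusive. For confined-motion detection the
analysis uses a 1 s frame interval and a 10-lag log-log window: at
`D = 0.035 μm²/s` inside a 1 μm confinement radius, the closed-form confined
MSD (`≈ a²(1 − e^(−4Dt/a²))`) shows that a 5-lag fit at 0.5 s sampling
barely leaves the linear regime (α ≈ 0.91), while 10 lags at 1 s sampling
put the curvature squarely inside the fit window (α ≈ 0.76). Diameter
stratification (e.g. the 4–8 μm band) filters tracks by median equivalent
diameter.

## FRAP analysis

The measurement ROI follows the droplet centroid frame by frame (carried
forward through frames where a deeply bleached droplet is not segmented).
The per-frame median intensity outside the droplet is subtracted by default,
so floor and plateau refer to droplet fluorescence rather than camera
offset. The bleach frame is auto-detected as the largest single-frame
fractional drop (overridable); a largest drop under 15% flags "no bleach
found". Traces are normalized to the mean pre-bleach intensity; double
normalization against a reference ROI (which cancels acquisition
photobleaching) is available but off by default, matching the single
pre-bleach normalization convention.

Recovery is fit with a single exponential
`I(t) = floor + (plateau − floor)(1 − e^(−k(t−t₀)))` — the minimal model
consistent with reporting `t₁/₂ = ln2/k` and a mobile fraction
`(plateau − floor)/(1 − floor)`; closed-form spot-FRAP solutions are
deliberately out of scope, and the lattice simulations serve as the truth
standard for what the exponential fit recovers. Two estimator biases are
worth knowing: the measured mobile fraction is low by roughly the bleached
area fraction (the bleached material redistributes over a finite droplet) and
by PSF mixing at the spot edge, so validation scenes use a bleach spot small
relative to the droplet (radius ~1/8 of the droplet radius) and large
relative to the PSF. Mobile fractions are clipped to [0, 1] with a flag when
the raw value is outside by more than 0.05; non-convergence yields a flagged
NaN fit, not an exception.

Cross-condition comparison reports the fold change of mean half-times with a
seeded percentile bootstrap (default 2000 resamples) over replicate fits;
length-series comparisons evaluate each condition's fitted recovery at a
fixed post-bleach readout time and report whether recovery decreases
monotonically with polymer length.

## Phase diagrams and dissolution

A condition cell is "condensates present" when segmentation finds at least
`min_count = 5` droplets with median equivalent diameter ≥ 1 μm — explicit
quantitative stand-ins for a by-eye call, and both CLI-exposed. The
dissolution score is the ratio of total condensate area after the treatment
(plus a settling window) to the area before it; the verdict threshold of 0.5
sits midway between the all-or-none outcomes the assay produces (fluid
fields dissolve to ~0, crosslinked fields persist at ~1).

## Validation scales

The test suite and the acceptance script exercise the full pipeline at these
problem sizes, chosen to keep a complete run within a few minutes on one
CPU: 50 single-fusion movies (SNR 10, diameters U(2,6) μm, η/γ = 0.5 s/μm,
0.25 s frames); three 320-frame mobility movies of six 5 μm droplets at
0.15 μm/px (≥5000 windows of length 20) at D = 0.035 μm²/s; FRAP lattices
with an 8 μm droplet at 0.2 μm/px over 240–300 frames; a 50-cell presence
grid at SNR 5; and 20-frame dissolution fields. Passing these shows the
estimators recover known parameters through realistic optics; it does not
exercise DIC contrast, uneven illumination, focus drift, droplet wetting or
shape irregularity, 3D sectioning, or segmentation at SNR below ~5 — real
data with those features may need the fixed-threshold mode and parameter
adjustments.

## Known limitations

- The recovery-model mismatch (exponential fit to diffusive recovery) is
  absorbed into tolerances rather than corrected; absolute `k` values are
  geometry-dependent and should only be compared at fixed geometry.
- MSD standard errors over overlapping windows understate correlation;
  confidence statements should rest on replicate movies.
- The tracker is nearest-assignment with a hard gate: it has no motion
  model, so it is not suited to dense fields with crossing trajectories.
- Volume inference treats droplets as spheres (equivalent-diameter cubes);
  wetted, flattened droplets violate this.
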