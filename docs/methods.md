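# Methods

This note documents the models implemented in `lgquant`, the defaults and
why they were chosen, the numerical conventions, and what validation on
synthetic data does and does not establish.

## Nuclei counting

The nuclear (DAPI) channel of a z-stack is filtered slice by slice with a
2D difference of Gaussians, `DoG = G(σ_small)∗I − G(σ_wide)∗I`. The wide
kernel acts as a local background estimate, the small kernel suppresses
sub-nuclear texture; blobs between the two scales become positive response
maxima. We deliberately orient the subtraction as small-minus-wide so that
nuclei are *bright* in the response — the opposite order produces a
sign-inverted band-pass in which nuclei would be minima, which defeats
thresholding "bright spots". Filtering is per-slice (2D) by default
because confocal stacks are strongly anisotropic and the counting
convention this package reproduces filtered each image of the z-stack
independently; a fully-3D mode (`filter_3d`) exists for near-isotropic
data.

Sigmas are expressed in µm and converted to pixels per axis through the
voxel spacing. Defaults are tied to the expected nuclear radius
(≈2.5 µm in lymph glands): `σ_small = 1.25 µm` (half the radius) and
`σ_wide = 5 µm` (twice the radius). These bracket the blob scale; they are
configuration, not constants.

The 3D response is thresholded once over the whole volume. The default
rule is Otsu; `quantile(q)` and `absolute(v)` are available. Ties at the
threshold are background (strict `>`): thresholding must be stable under
the affine rescalings Otsu is invariant to. Bright spots are 3D connected
components (26-connectivity by default), filtered to a physical volume
window (4–400 µm³ by default, i.e. equivalent radii ≈1–4.6 µm), and
optionally split by a marker-controlled watershed on the Euclidean
distance transform (smoothed, peaks at least 2 µm apart) — dense
hematopoietic tissue makes merged components common. Centroids are
component centres of mass in physical coordinates; the equivalent radius
is `(3V/4π)^{1/3}`. Labels are assigned in raster order of each
component's first voxel, so output ordering is deterministic.

## Marker classification and indices

For each detected nucleus the mean intensity of each marker channel is
taken over all voxels whose physical distance to the centroid is at most
`radius_factor × r̄`, where `r̄` is the arithmetic mean of the detected
equivalent radii and `radius_factor = 1.5`. A single global radius (rather
than per-nucleus radii) is the default because the search sphere is meant
to capture membrane/cytoplasmic stains around nuclei of similar size; a
per-nucleus mode exists behind a flag. The mean (not max or sum) is used
because it is stable under border clipping and intensity saturation.
Border nuclei are kept with clipped spheres, since indices are reported
over whole lobes; an exclusion flag exists.

Positive calls use a threshold over the distribution of per-cell sphere
means — Otsu by default, with quantile/absolute rules and per-marker
overrides. "At or above threshold" counts positive (ties are positive).
The differentiation index is the exact rational
`positives / total` (kept as a `Fraction` alongside its float), optionally
restricted to an ROI by centroid membership. An empty restriction is an
error, never an index of 0. PSC cell counts and circulating hemocyte
subset counts are the same operation applied to the relevant marker.

## Permeability-barrier assays

The single-dye readout is the arithmetic mean intensity over ROI voxels.
The dual-dye readout is the sample Pearson correlation of the two dextran
channels over ROI voxel pairs — computed over voxels, not cells, matching
ROI-pixel semantics of standard colocalization plugins. Zero variance in
either channel makes r undefined and raises, rather than reporting 0.
Saturated voxels are included by default (acquisition for these assays
normalizes the out-of-tissue medium to saturation); a flag excludes them.
`barrier_contrast = r_PSC − r_nonPSC` summarizes a specimen: negative
means intact. ROIs may be volumetric or single-slice; both are supported
and volumetric is the default.

## Group statistics

Two-sample comparisons use the unpaired Welch t-test with
Welch–Satterthwaite degrees of freedom and a two-sided p. Significance
tiers follow the source legend this pipeline reproduces —
`*** p<0.001, ** p<0.01, * p<0.1` — including the unusually lax single
star; a conventional 0.05/0.01/0.001 scheme is selectable. No
multiple-testing correction is applied by default (none is applied in the
workflow being reproduced). Fold change is a ratio of group means and
requires a positive reference mean. One specimen contributes one
observation.

## Synthetic scenes

The generator emulates the features of lymph-gland confocal data that the
pipeline actually exercises:

- **Nuclei** are isotropic Gaussian blobs, `σ = r/2`, so intensity falls
  to ~60% of peak at one radius; radii are drawn U(2, 3) µm. Blobs rather
  than hard spheres keep the DoG response analytic and the
  radius-recovery oracle simple.
- **Markers** are Gaussian shells centred at the nuclear radius with
  thickness 0.25 r, emulating surface stains such as P1 — which is why
  the search sphere is wider than the nucleus.
- **Dyes** label every cell surface identically; inside a single
  ellipsoidal exclusion region (the PSC) the large-dye signal is
  multiplied by an attenuation factor (default 0 = complete exclusion).
  Attenuation is multiplicative, not subtractive, so the intact/broken
  contrast survives noise. A constant dye background stands in for dye in
  the medium.
- **Placement** is rejection sampling with a hard minimum pairwise
  separation (default 6 µm, i.e. non-overlapping at the maximum radius);
  a packing-feasibility bound (38% exclusion-volume fraction, the
  random-sequential-addition saturation density) rejects impossible
  requests up front. PSC nuclei are placed inside the exclusion ellipsoid,
  all others outside. Marker memberships are drawn without replacement at
  exact counts, so the ground-truth index is exactly the requested
  fraction.
- **Noise** is `Poisson(photon_scale · signal)/photon_scale` shot noise
  plus additive Gaussian read noise, clipped to `[0, saturation]`.
  Defaults: `photon_scale = 2` photons per intensity unit,
  `read_sigma = 2`, saturation 255, nuclear amplitude 60 over a background
  of 4–8 — peak SNR ≈ 11, a mid-quality confocal acquisition. These are
  chosen as realistic operating conditions for the pipeline, not as
  claims about any particular dataset; recovery degrades gracefully as
  photon_scale is lowered.
- **Geometry** defaults to ~300 nuclei in a (40, 192, 192)-voxel stack at
  (1.0, 0.3, 0.3) µm spacing. Benchmarks scale the lateral field with the
  cell count (~450 µm³ of tissue per nucleus, 32 µm depth) so density is
  constant from 50 to 500 nuclei.

What the generator does **not** model: optics (PSF convolution, spherical
aberration, depth attenuation), photobleaching, cell movement, irregular
nuclear shapes, chromatin texture, or spatially correlated background
beyond a linear lateral gradient. Passing recovery tests on these scenes
therefore demonstrates correctness of the measurement chain under
known-truth conditions, not segmentation performance on arbitrary real
tissue; on real data the detection and threshold parameters remain the
user's responsibility.

## Numerical conventions

- Arrays are `(z, y, x)`, 0-based; the centre of voxel *i* is at physical
  coordinate `i × spacing`. Public coordinates are physical µm.
- Polygon ROIs live in continuous pixel coordinates where voxel *i* spans
  `[i, i+1)`; a voxel is inside iff its centre `i + 0.5` is strictly
  inside the polygon (half-open rule: an integer-vertex rectangle covers
  exactly its area). Vertices at half-integer coordinates tie-break to
  outside.
- Missing pixel-size metadata in a TIFF falls back to isotropic 1 µm with
  a logged warning rather than an error (pixel-unit analyses remain
  valid).
- Renders accumulate nuclei in a canonical spatial order, so noise-free
  output is bit-identical under any relabeling or reordering of the
  ground-truth list. All randomness flows from one root seed through
  named substreams (`SeedSequence` keyed by stage name), so adding a
  stage never perturbs another stage's draws.
- CSV floats are rounded to 6 significant digits at write time, which is
  what makes repeated pipeline runs byte-identical.
- Degenerate inputs fail loudly: Otsu on a constant image, Pearson with a
  zero-variance channel, an index over zero cells, and a Welch test with
  two zero-variance groups all raise typed errors instead of returning a
  default.

## Benchmark problem sizes

The bundled experiments use scenes of 50–500 nuclei for count recovery
(noise-free and noisy), 80-nucleus scenes across marker fractions
{0.1, 0.3, 0.6} with 10 seeds each for index recovery, 100-nucleus scenes
for the two-condition fold-change experiment (10 specimens per condition,
true indices 0.06 vs 0.30), and 40-nucleus niche scenes for the dual-dye
discrimination benchmark (20 intact + 20 broken). These sizes keep a full
benchmark run to well under a minute per experiment on one CPU while
leaving each statistic comfortably powered.

## Known limitations

- The watershed splitter assumes roughly convex nuclei; elongated or
  lobed nuclei may be over-split. Disable with `split_touching=False`.
- Otsu marker thresholds need both populations present; a specimen with
  (near-)zero marker-positive cells should use an absolute threshold.
- ROI restriction is by centroid membership, so a cell straddling an ROI
  boundary is counted wholly in or out.
- OME-TIFF support covers plain (C)ZYX stacks; proprietary microscope
  container formats are out of scope.
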