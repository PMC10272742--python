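# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic validation does and does not establish.

## Masking

The tissue mask is produced by a fixed chain: linear contrast stretch
saturating 0.35 % of pixels (0.175 % per tail, the classic interactive
default; configurable via `MaskingParams.contrast_saturation`), a 3×3 mean
filter, Huang fuzzy-entropy thresholding, a disk-median filter of radius
`median_radius_um` (majority vote on the binary image, closing small gaps),
and removal of 8-connected components with area strictly below
`min_particle_area_um2`. An all-background result is legal.

The vascular mask chain is: 3×3 median despeckle, 3×3 mean smooth,
convoluted background subtraction — the image minus its Gaussian blur,
clamped to [0, 255] — pixel-wise multiplication by the tissue mask, then an
auto-threshold chosen by the user. The Gaussian scale is derived from the
radius of the biggest object in the image as
`σ_px = background_radius_um / (2 · calibration)`; half the named radius
keeps the blur scale above every vessel width while remaining conservative,
and the factor is exposed (`sigma_factor`) for users who match other
conventions. Thresholding polarity is bright-foreground throughout: pixels
strictly greater than the returned integer threshold are foreground
(dark-field fluorescence).

Three histogram thresholds are implemented from their defining criteria and
are unit-tested against exhaustive brute-force optimisation over all 256 cut
points: Otsu (maximal inter-class variance), Huang–Wang (minimal fuzzy
entropy with membership `1/(1+|x−μ_class|/C)`, `C` the occupied intensity
span), and "default" = iterative IsoData (the mean-of-means fixed point,
the de-facto meaning of that menu entry in common image-analysis software).
Degenerate single-bin histograms return that bin's index.

A practical caveat found while validating on phantoms: histogram thresholds
need a tissue/glass histogram that is actually separable. When the region
outside the tissue is as noisy as the tissue itself, Huang's criterion can
place the threshold inside the glass band; on real slides the glass is
nearly black and homogeneous, which the phantom generator now reproduces.

## Local thickness

The thickness at pixel `p` is the diameter of the largest disk fully inside
the foreground that covers `p`, sampled on the pixel-center lattice:
`2·max{r(q) : |p−q| ≤ r(q)}` with `r(q)` the Euclidean distance from `q` to
the nearest background pixel. The implementation computes the EDT, discards
every center whose disk is contained in a neighbour's
(`r(q') ≥ r(q) + |q−q'|`, an exact reduction), and paints the surviving
disks taking the maximum. It agrees exactly with a per-pixel brute-force
search in the tests. Under this convention an even-width slab measures
exactly its width, a rasterised radius-10 disk measures 20.1 at the center,
odd widths overestimate by up to one pixel, and an isolated single pixel
measures 2 px-equivalents; the up-to-one-pixel overestimate matches the
behaviour of the widely used local-thickness plugins.

## Skeleton graph

The mask is skeletonized with a topology-preserving 2D thinning
(scikit-image). Skeleton pixels are classified by 8-neighbour count
(1 endpoint, 2 slab, ≥ 3 junction); 8-adjacent junction pixels merge into
one junction node; isolated pixels are degenerate one-pixel clusters with
no branch; slab-only cycles become closed loop branches. Branch paths
include their terminal node pixels.

**Branch length.** The default estimator resamples the traced path with
anchors every 4 pixels and sums Euclidean distances between anchors. A pure
chamfer sum (1 per orthogonal, √2 per diagonal step) is available as
`length_method="chamfer"`, but it over-estimates digitized path length by
4–8 % at orientations between the lattice axes (measured on straight tubes
at 15–30° and on sinusoids), which would dominate the error budget of
length and tortuosity; the anchored-polyline estimator is
orientation-unbiased to < 1 % and reproduces axis-aligned and diagonal
digital lines exactly (anchors on a straight line are collinear).

**Per-branch quantities.** `L` as above; `E` the Euclidean distance between
the path's end pixels; tortuosity `T = L/E` (arc-chord ratio, 1.0 for a
straight vessel); `d̄` the unweighted mean of thickness values along the
path; branch area `d̄·L`. For closed loops `E` is ill-defined and is
reported as the maximum pointwise chord with the branch flagged; loops
count as one branch. A skeleton pixel with zero thickness raises an
internal-consistency error.

**Pruning.** A branch is removed when its length is below the prune-ends
threshold and at least one end is a tip (degree-1 node). The default is a
single pass over the graph as built, after which junctions left with
exactly two incident branches merge them (lengths add, `E` is recomputed
from the new ends, `d̄` recombines length-weighted); `iterative_prune`
repeats until stable. Node counts are recomputed from the surviving graph:
degree-1 nodes are endpoints, degree ≥ 3 junctions; pruning can delete an
entire small component, which then no longer counts as a cluster.

**Compartments.** Each branch is assigned by `d̄` against the separation
threshold; ties (`d̄ == θ`) go to the "above" (macrovascular) compartment.
The partition is exhaustive and exclusive, so Σ-length, Σ-area and branch
counts are exactly additive across compartments. Node and cluster counts
are properties of the full skeleton and are reported for it only.

**Read-outs.** Densities divide by the tissue area of the tile (mm²);
tiles with empty tissue are skipped before any computation. The vascular
density is an estimate (`Σ d̄·L`, not a pixel count) and can overshoot on
dense plexi; it is capped at 100 % with the raw value retained
(`vascular_density_raw_pct`). Means over empty branch sets are emitted as
missing (NaN → empty CSV cells), never 0, so per-sample averages are not
biased; the sample summary reports mean ± SEM over non-missing tiles and a
single contributing tile yields a missing SEM. The tile-level mean vessel
diameter is the unweighted mean over branches of `d̄`; a length-weighted
variant is exposed (`diameter_weighting="length"`).

## Co-staining

Co-channel masks are multiplied with the raw channel-1 mask first; the
identical correction chain (tissue gate, hole filling) and the full
skeleton pipeline are then re-run on the overlap, and each read-out is
reported as `100 · overlap / primary`. Ratios with a zero or missing
primary read-out are missing, never 0 or infinite. Ratios are computed for
the whole overlap graph (no compartment split within the overlap) by
default. Up to two co-channels (2 and 3) are supported.

## Evaluation

Confusion counts are taken over every pixel of the tile; Dice, accuracy,
sensitivity and specificity follow their count definitions exactly. Scores
with zero denominators are missing rather than 0 or 1.

## Phantom generator

`generate_network` paints disk-capped tubes of known width along analytic
centerlines (straight, sinusoid, or correlated random walk), adds Gaussian
noise (clipped to [0, 255]) with separate levels for vessels, tissue
autofluorescence and the near-black glass outside the tissue, and returns
exact ground truth: per-tube width, analytic length and arc-chord
tortuosity, painted area, and network totals. All randomness flows from
one explicit seed through one generator; identical seeds give bit-identical
output. Centerlines sit on half-integer coordinates so even widths
rasterise exactly; straight tubes default to orientations in
{0°, 45°, 90°, 135°}, where the digitized centerline length equals the
analytic length — the phantom is a calibration target, and restricting to
digitization-exact angles keeps its ground truth exact (arbitrary angles
via `angle_set=None`; the sinusoid and random-walk modes cover oblique
orientations). Sinusoid defaults (amplitude 8 px, period 150 px, analytic
tortuosity ≈ 1.03) emulate the gentle undulation of microvessels.
`avoid_tile_boundaries` keeps tubes clear of a tile grid so tiled
quantification is free of cut artifacts.

What the phantoms do **not** emulate: point-spread blur, vignetting and
stitching seams, staining heterogeneity along a vessel, true branching trees
(tubes are unbranched), crossing/overlapping vessels, and partial-volume
effects of section thickness. Passing the phantom recovery tests therefore
shows the measurement chain is correct on well-segmented, resolvable
vessels; it does not bound errors from imperfect segmentation on real
slides, and vessels crossing tile boundaries remain under-measured (an
inherent property of tile-wise analysis that shrinks with tile size and is
mitigated by analysing the microvascular compartment).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `calibration_um_per_px` | required | spatial calibration; user-supplied, never read from TIFF tags (a mismatching tag logs a warning) |
| `separation_threshold_um` | 10 | compartment cutoff on `d̄` (brain example value) |
| `close_radius_um` | 3 | hole-fill radius (brain example value) |
| `prune_threshold_um` | 5 | endpoint-branch pruning length; in practice ≈ half the typical vessel diameter |
| `n_channels` | 1 | 1–3; ≥ 2 enables co-staining ratios |
| `length_method` | resampled | branch length estimator (see above) |
| `resample_spacing_px` | 4 | anchor spacing of the default estimator |

Phantom-validation runs in the tests and the acceptance script use tubes of
width 4–16 px, lengths 150–220 px on 360–460 px canvases, with
`prune_threshold_um = 10` (≈ 0.6 of the largest width, suppressing cap
spurs); these sizes keep each run in seconds while leaving every contract
measurable.

## Known limitations

- 2D only; read-outs from single sections of a 3D network are biased by
  section thickness and missing out-of-plane branching.
- Vascular density is a skeleton-based estimate, not a pixel count; compare
  against other tools with care.
- Tile-wise analysis truncates vessels at tile cuts; lengths of vessels
  larger than a tile are under-estimated.
- The tile loop is sequential; tiles are independent and the loop is
  embarrassingly parallel if needed.
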