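# Methods

This note documents the models, conventions and numerical choices behind
`cordmorph`, and what the synthetic benchmarks do and do not establish
about real confocal data.

## Imaging model and coordinate conventions

All image-facing code assumes transverse sections imaged as grayscale
stacks with isotropic in-plane sampling. The default geometry is the
high-magnification operating point the pipeline is designed for:
0.31 × 0.31 μm pixels and 0.85 μm slice spacing (configurable
everywhere). Coordinates put the origin at the top-left pixel centre
with x along columns and y along rows; physical position is index ×
pixel size in μm. Orientation angles are measured from the +x axis
toward +y with a 180° period (axial quantities). Sections are assumed
pre-oriented so that the image y axis is the ventro-dorsal axis.

## Central-canal segmentation and ellipse fit

Per slice: Otsu's global threshold produces a foreground mask;
8-connected components smaller than `min_component_px` are discarded and
the surviving component whose centroid lies nearest the frame centre is
selected. `min_component_px` defaults to 200 px (≈ 19 μm² at
0.31 μm/px), enough to reject nucleus-sized specks while keeping small
canals; it is a free parameter, not a biological claim.

A canal cross-section is accepted only if its contour is *closed*,
operationalized topologically: the component must enclose at least one
background hole strictly inside the frame (the dark lumen inside the
bright ependymal ring). Components without a hole are accepted only if
they are effectively solid (solidity ≥ 0.9), so a filled disc — a canal
whose lumen is below resolution — still passes, while a ring with an arc
gap does not. Slices failing segmentation or closure are excluded from
all downstream ellipse statistics and counted per reason
(`no-component`, `truncated`, `not_closed`, `degenerate`); the
accounting reconciles exactly with the number of slices in.

The ellipse is fitted to the *lumen-filled* outer region by image
moments: with covariance eigenvalues λ₁ ≤ λ₂ of the filled pixel set
(plus the px²/12 within-pixel variance term), the full diameters are
d = 4√λ, which is exact for an ideal filled ellipse. Orientation is the
major eigenvector's angle; eccentricity √(1 − (d_min/d_max)²); the area
is reported both analytically (π·d_min·d_max/4) and as the pixel count ×
px², because on real tissue the two differ whenever the region is not a
perfect ellipse. A moments fit was chosen over iterative conic
least-squares because it is deterministic, has no initialization or
convergence behaviour, and is well defined on any filled region.

Group mean shapes average d_min and d_max arithmetically and the
orientation circularly on doubled angles (axial statistics, period
180°), with centres aligned to the origin — shape-only averaging.

## Cell detection and radial mapping

The cell channel is normalized per slice: min–max rescale to [0, 1]
followed by histogram equalization through the normalized CDF (256
bins) with the lowest occupied bin mapped to 0. The cdf-min subtraction
matters: without it a near-constant background maps to its own
cumulative mass (≈ 1) and would survive any high threshold. A constant
slice has no defined rescale and is zeroed with a logged warning.

Binarization uses a single global threshold at 95% of the whole-stack
maximum, with ties counted as foreground. Because equalization is
rank-based, bright cells in a slice map to the top of the range
regardless of their absolute brightness, while up to ~5% of background
voxels can also clear the threshold on noisy slices; those form small
speckle components that the volume filter removes.

3D connected components use 26-connectivity (6/18 selectable; the
generator's compact blobs make the three agree). Objects with strictly
fewer than 6 000 voxels are removed, so exactly 6 000 survives; the
voxel count is the canonical parameter and the μm³ equivalent
(6 000 × 0.31² × 0.85 ≈ 490 μm³) is derived from it. Centroids are
unweighted voxel means. The distance to the canal is in-plane (x, y)
against the canal centre of the nearest valid slice within ± 2 slices
(`z_window`); cells without a reference are flagged `no-reference`,
excluded from distance statistics and counted.

Zones: proximal ⇔ d ≤ 100 μm, distal ⇔ 100 < d ≤ 230 μm, outside ⇔
d > 230 μm. Zone percentages are taken over proximal + distal only,
with the outside bucket reported separately so the handling of far
cells is explicit. Distance distributions are right-continuous ECDFs.
Touching cells merge into one component and are counted once — the
method's known under-segmentation is reproduced, not patched with a
watershed, and is asserted as expected behaviour in the tests.

## Landmark morphometry

The 14 lengths are taken as given (manual placements arrive as data; no
automatic landmarking). Derived quantities: AP/T, AW/PW, RVH/RDH,
LVH/LDH, VGC+DGC, the canal position VWC/(VWC+DMS) ∈ [0, 1] (larger =
more dorsal), and a commissure-size field. The commissure size has no
canonical formula; it defaults to (VWC+DMS)/2 and is pluggable
(`half_sum`, `sum`, `vwc`) — a package convention, clearly
non-canonical. Ratios with zero denominators yield NaN plus the name of
the offending field; they are flagged and excluded from summaries, never
silently dropped.

Repeatability uses the per-section coefficient of variation over
replicate placements, COV = 100 · sample sd / mean, aggregated per
landmark as mean ± sd across sections and gated at mean COV < 5%.
Sample (n−1) standard deviations are used throughout, including in the
`mean ± sd [min, max]` group summaries (sd undefined at n = 1). Missing
replicates are an error, not an imputation.

## Statistics layer

Two-group comparisons are gated by Shapiro–Wilk per group at α = 0.05:
both groups compatible with normality → two-sided Student's t (classic
equal-variance; Welch selectable), otherwise two-sided
Wilcoxon–Mann–Whitney. Any single non-normal group routes to the rank
test (the conservative reading). The screening cascade runs a one-way
ANOVA per parameter against the factor and admits only ANOVA-significant
parameters into a MANOVA using Pillai's trace (other statistics
selectable through statsmodels); with a single admitted response the
MANOVA reduces to the ANOVA, and a singular response covariance raises
an error naming the most collinear pair. Correlations use Kendall τ-b
(tie-corrected — morphometric lengths tie after rounding) with bands
negligible < 0.1 ≤ low < 0.3 ≤ moderate < 0.5 ≤ strong < 0.7 ≤ highly
strong, and τ = 1 perfect.

Star coding uses strict thresholds `***` < 0.001, `**` < 0.01,
`*` < 0.05, and a trend mark `●` for 0.05 ≤ p < 0.1; boundary values
fall into the weaker adjacent tier (p = 0.05 → `●`, p = 0.1 → none).
No multiplicity correction is applied by default (a Benjamini–Hochberg
pass is easy to add downstream but is deliberately not silently on).
Sections are the statistical unit, nested within animals; animal-level
aggregation is a caller-side sensitivity analysis, not the default.

## Synthetic data: what it emulates, and what it does not

`CanalImageSpec` renders each slice as a bright elliptical ependymal
ring with a dark lumen on a (optionally noisy) background. The planted
ellipse is defined as the **outer** ring contour and the ring extends
inward by `ring_thickness_um` (< d_min/2), so the planted parameters
are exactly the contour the fit recovers after lumen filling —
parameter recovery is well-posed by construction. The generator rejects
geometries that do not fit the frame with a 2 px margin.

`CellFieldSpec` plants blobs as superlevel sets of an anisotropic
Gaussian — the `volume_voxels` voxels nearest the requested centre in
physical distance, rendered at a uniform peak intensity. Uniform cores
are deliberate: histogram equalization is rank-based, so a graded blob
interior in a low-clutter slice would be spread uniformly over [0, 1]
and the 95% threshold would retain only its top few percent; a
uniform-intensity core maps to the slice maximum as one bin and the
above-threshold voxel count equals the planted volume *exactly*, which
is what makes the 5 999/6 000 filter boundary testable. Cells may not
overlap each other (beyond a configurable fraction) or the canal
footprint; ground truth records exact voxel-set centroids, volumes and
radial distances.

`CohortSpec` draws section lengths as Gaussian noise (truncated at
zero) around per-landmark baselines, with additive age (applied to
8wo), sex (applied to M) and per-region effects. The default baselines
and sds are the young-adult male operating point of the emulated
cohort; the default design is 2 ages × 2 sexes × 4 regions × 2 animals
× 22 sections. Replicate placements add proportional Gaussian jitter
controlled by a target COV percentage.

What passing the synthetic suite does **not** show: robustness to
uneven staining, slicing-induced canal deformation and collapse,
fluorescence bleed-through, anisotropic PSF blur, or densely packed
cells; background/foreground intensity statistics are free parameters
of the generator, not measurements. Results on real tissue depend on
those factors and on manual landmark quality in ways the generator does
not emulate.

## Benchmark problem sizes

The validation harness (`cordmorph.validation`) sizes its runs so each
check is decisive yet quick: the ellipse grid covers 100 noise-free
cases (d_min 10–30 μm × d_max 30–60 μm × 4 orientations) on 230² px
frames; cell-count recovery plants k ∈ {0, 1, 8, 25} cells of 6 000
voxels among 50 distractors of 500 voxels on 500² × 20 stacks with
background noise; type-I calibration uses 1 000 null cohorts at
n = 50/group (binomial s.e. ≈ 0.007 around 0.05) and the power check
300 cohorts with a 1-sd AP age effect at n = 100/group, where the
theoretical t-test power is ≈ 1. Determinism is asserted byte-for-byte
over all pipeline outputs, excluding only the run log's wall-clock
timestamp.
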