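# Methods

`colonyquant` quantifies fluorescently labeled cell colonies in
stitched 4x microscopy montages: fixed-and-stained wells, live wells,
and whole lung tissue sections carrying metastatic colonies of two
reporter-labeled subpopulations (DsRed and GFP). This note describes
the models and procedures, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was open.

## Image model and scale conventions

All processing happens on floating-point images normalized to [0, 1]
(8/16-bit inputs divided by their dtype maximum). Stitched montages are
acquired at 1.346 um/px and reduced by 50% per linear dimension on load
via block-mean resampling, giving the working pitch of 2.692 um/px;
odd trailing rows/columns are dropped (13346 → 6673). One binarized
pixel at native pitch covers 1.346² ≈ 1.81 um². Structuring-element
radii in the configuration are given in microns and converted through
the pitch, so one config serves both scales.

Morphological conventions: 8-connectivity for object labeling and
regional extrema, 4-connectivity for watershed flooding (ridges
separate diagonal neighbors); reflect padding for filters; a constant
image has no regional extrema; watershed ties at equidistant ridge
pixels are resolved by flooding order, so basin boundaries carry a
±1 px convention. All operators are deterministic.

## Fixed-cell pipeline

Each channel passes through the shared preprocessing chain: white
top-hat (background and vignetting removal), Gaussian smoothing
(default sigma 2 px at colony scale, 1 px at nucleus scale), percentile
contrast stretch (1 / 99.9 by default) and binarization. The default
binarization is a fixed threshold of 0.5 on the stretched scale — the
stretch exists precisely to put fluorescent regions above a fixed
threshold — with Otsu available by configuration.

Two numerical guards make the chain behave on degenerate inputs:

* **Noise floor.** The threshold, mapped back to the raw intensity
  scale, is never allowed below `median + 6 x MAD-sigma` of the
  smoothed image. On a signal-free channel the percentile anchors
  collapse into the noise distribution and a plain stretch would
  binarize ~35% of the pixels; the floor returns an empty mask instead,
  while genuinely sparse signal (a handful of cells in a whole montage)
  stays far above it.
* **Top-hat element size.** An opening levels any plateau wider than
  its structuring element, so the element must exceed the largest
  feature to keep. Colonies reach ~120 um radius by imaging day 4;
  the colony-scale default is therefore a 200 um disk (nucleus scale:
  15 um). For large radii the disk is opened with scikit-image's
  decomposed ("sequence") footprint, a slightly octagonal but much
  faster approximation; the exact Euclidean disk is available per
  config and is the reference in the unit tests.

Colony segmentation follows the classic distance-transform watershed:
the binarized DAPI mask is Euclidean-distance transformed, inverted
with the background raised above the maximum so colony centers become
catchment basins, shallow basins are filled with an h-minima transform
(default h = 4 px of distance — below the ~8 px saddle depth between
overlapping colonies, above discretization ripple), and the watershed
assigns every foreground pixel to a colony. Objects below four nominal
cell areas are discarded (the nominal cell area is pi r² at the
configured 7 um nucleus radius). Nuclei are segmented with the same
chain at nucleus-scale parameters (h = 0.7 px, minimum 8 px).

Fused "super-colonies" and sheet-like growth cannot be split into
their original clonal units; they are reported as single objects.

Each nucleus is assigned to the colony label under its centroid
(robust to nuclei straddling colony boundaries); cell count is the
number of assigned nuclei. Colonies are classified from the binarized
reporter masks: a class is called when at least half of the colony's
pixels (configurable) overlap the channel mask; both → `double`,
neither → `none`. Colony area is measured on the DAPI-derived label,
not the reporter mask.

Ki-67 scoring compares each nucleus with the binarized CY5 stain: the
overlap fraction is the share of nuclear pixels inside the stain mask,
and a nucleus is positive only when the fraction is **strictly**
greater than the threshold (default 0.25). The per-colony Ki-67 index
is the fraction of constituent cells scored positive; the summary
statistics report its cumulative frequency, the fraction of colonies
with index strictly above 0.8, and the fraction of completely
non-proliferative colonies (index 0, the curve's y-intercept).

## Live-cell pipeline

Without nuclear staining, the same distance-transform watershed is
applied directly to the binarized GFP/RFP reporter channels, each
segmented independently. Colony area stands in for size; because areas
and cell counts are well correlated, an ordinary least-squares line
`cell_count ~ area_px` fitted on a fixed-cell run of the same cell
line (free intercept; at least 3 points with non-constant areas)
converts areas to estimated counts, clamped at zero. The intercept is
left free because the area of a detected blob includes a
smoothing-dependent halo, which a through-origin fit would fold into
the slope; the calibration JSON records slope, intercept, r² and n.

## In vivo two-part pipeline

The DAPI channel only delineates lung tissue: heavy Gaussian blur
(sigma 15 px), Otsu threshold, morphological closing (5 px), largest
connected component, hole filling. It plays no role in lesion
segmentation.

**Part 1 (macrometastases).** The reporter channel is top-hat filtered
(250 um element) *before* any lung restriction — masking first would
manufacture a bright background ring along the tissue boundary — and
then blurred strongly enough that lesions of a few cells vanish. The
blur sigma is computed, not hard-coded: a disk of radius r blurred by
sigma retains a peak fraction `1 − exp(−r²/2σ²)`, and
`σ = 1.2 r_max / sqrt(2 ln 2)` (r_max the micro/macro size cut) leaves
a solid disk at the cut with ~40% of its amplitude while sparse
few-cell clusters — whose blurred peak is set by their total flux, not
their extent — retain far less. The contrast stretch of the blurred
image is anchored to the 99.9th percentile of the *pre-blur* top-hat
image inside the lung, so this attenuation survives on the stretched
scale: a section containing nothing but micrometastases produces no
macro mask. The extended-maximum transform (h = 0.1 on the stretched
scale; the blurred relief is smooth, so h needs only to exceed
residual ripple ~0.02 while staying below the ~0.2 saddle between
adjacent lesions) marks the dense lesion cores, which seed a watershed.
The watershed domain is the blurred macro mask unioned with the
sharp-foreground components overlapping it, so reported lesion extents
follow the true (unblurred) lesion boundary — the boundary the
exclusion rule measures from; a domain of the blurred mask alone
systematically under-covers lesion edges by a few pixels and would
bias every boundary distance. Lesions below the macro minimum area
(equal to the micro maximum) are dropped. Distance transforms are
unsuitable as the seeding mechanism here because lung tissue intensity
is far more variable than well-plate DAPI; the extended-maximum
transform replaces them.

**Part 2 (micrometastases).** Macro pixels are zeroed and the
remainder re-scanned with the light chain (30 um top-hat, sigma 1 px).
Candidate components are consolidated with a 3 px closing (the cells
of one sparse seeding event join into a single candidate) and then
refined to their half-peak (FWHM) footprint on the *unsmoothed*
top-hat image: the half-maximum contour of a compact blob is
insensitive to the global contrast stretch and to the smoothing
kernel, which keeps boundary measurements accurate to about a pixel.
The refined footprint drives the size window (default 2.5–40 nominal
cell areas) and the exclusion rule: any candidate whose minimum
boundary-to-boundary Euclidean distance to a macro lesion — computed
from the distance transform of the macro label map — is ≤ 40 px
(107.7 um at working pitch) is flagged `near_macro` and never counted,
since it cannot be distinguished from cells migrating out of the
neighboring colony. Boundary distance is used rather than centroid
distance, which would misbehave for large lesions. Candidates whose
centroid falls outside the lung mask are flagged `outside_lung`.
GFP and RFP are processed independently; the exclusion rule acts
within a channel, and a lesion positive in both channels is reported
per channel.

## Statistics

Colony-size histograms are reported as probability densities
(integrating to 1), binned on log-spaced edges by default because the
distributions are right-skewed; replicate wells or mice binned on
common edges are averaged with per-bin standard deviations. Median
differences use the two-sided Wilcoxon rank-sum test: the exact null
distribution when the smaller group has ≤ 8 observations and no ties,
otherwise the tie-corrected normal approximation without continuity
correction (so identical samples report exactly z = 0, p = 1).
Multi-group comparisons use the Kruskal-Wallis H test with tie
correction (all-tied inputs return H = 0, p = 1 directly). Per-well
Ki-67 summary fractions are compared with an unpaired Welch t-test,
as equal variances across treatment arms cannot be assumed.

## Synthetic-data generator

The generator is the package's ground-truth oracle. It renders, at the
2.692 um working pitch, Gaussian-blob "cells" (nucleus radius 7 um;
blob width chosen so the half-maximum radius equals the nucleus
radius) grouped into colonies on a jittered hexagonal packing with
center spacing 3.5 nucleus radii, on a background of level 0.08 with a
quadratic vignetting field of amplitude 0.05 (to exercise the top-hat)
and additive Gaussian noise of SD 0.02. Fixed wells render nuclei in
DAPI, whole-colony soft-disk footprints in the class's reporter
channel, and CY5 blobs at the nuclei drawn Ki-67-positive
(class-specific positive fractions, default 0.9 for DsRed and 0.5 for
GFP). Live wells render reporter footprints only, growing in area by a
fixed factor (default 1.5) per timepoint. Lung sections render a
two-lobe ellipse tissue with textured DAPI autofluorescence, macro
lesions as soft plateaus (radius 24–38 px) with interior cell texture,
and micro clusters of 3–8 cells; clusters can be placed at exact
boundary gaps from a reference lesion (placement iterates until the
measured footprint-to-footprint distance matches the request within
half a pixel, and the measured value is what the truth table stores).

Truth footprints are defined as the pixels where an object's own
noiseless signal reaches half the blob amplitude — the same contour a
half-maximum binarization of the rendered image recovers — so truth
areas and truth boundary distances are directly comparable with the
pipeline's measurements. Identical seed and parameters give
bit-identical images and truth.

What the generator does **not** emulate: optical PSFs, stitching seams
and tile-edge shading, autofluorescent debris, intensity variation
within a reporter class, anisotropic or three-dimensional structure,
and cell shapes beyond isotropic Gaussians. Passing the recovery
suites therefore demonstrates that the algorithmic chain is correct
and self-consistent under the stated imaging regime, not that the
default parameters transfer to any particular microscope; on real
data the config (thresholds, h values, area cuts) is the tuning
surface, which is exactly why every one of them is exposed.

## Problem sizes used in the test and acceptance runs

Synthetic wells are 512 x 512 px with 12 colonies of ≥ 4 cells
(median ~7); lung sections are 640 x 768 px with up to 4 macro and
6–8 micro lesions. These sizes keep a full multi-seed recovery suite
fast while leaving every geometric relation (colony overlap, blur
attenuation, the 40 px exclusion distance) at the paper-scale pixel
pitch; the montage-reduction check runs once at the full native
13346 x 12300 size.

## Known limitations

* Fused colonies and confluent sheets are single objects by design.
* The micro/macro size cut and the Part-1 blur are coupled; moving the
  cut re-derives the blur sigma, but extreme cuts (micro_max within a
  factor ~1.5 of real lesion sizes) narrow the attenuation margin.
* The exclusion distance is measured at pixel resolution; distances
  within ~1 px of the threshold can fall on either side.
* Intensity-based (non-binary) protein quantification, cell tracking
  across live timepoints, 3-D reconstruction, and organ-specific
  tuning beyond lung are out of scope.
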