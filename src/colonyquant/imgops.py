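"""Channel-agnostic morphological and segmentation primitives.

Every pipeline in this package (fixed-cell wells, live wells, lung
sections) is a composition of the operators defined here: top-hat
background correction, Gaussian smoothing, percentile contrast
stretching, binarization, the Euclidean distance transform, h-minima /
extended-maximum transforms, and marker-controlled watershed
segmentation.

Conventions
-----------
* All intensity processing happens on floating-point images normalized
  to [0, 1]; 8/16-bit inputs are divided by their dtype maximum on load
  (see :mod:`colonyquant.io`).
* Regional extrema and object labeling use 8-connectivity; watershed
  flooding uses 4-connectivity, so ridge lines separate diagonal
  neighbors.
* Filters use reflect padding at image borders.
* A constant image has no regional extrema (strict-plateau convention).
* All operators are deterministic: identical inputs yield bit-identical
  outputs.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology, segmentation
from skimage.filters import threshold_otsu

#: Pixel pitch, in microns per pixel side, of a 4x stitched montage after
#: the 50% size reduction applied on load (native pitch 1.346 um).
DEFAULT_PITCH_UM = 2.692

_EXTREMA_FOOTPRINT = np.ones((3, 3), dtype=bool)  # 8-connectivity


class ParameterError(ValueError):
    """An operator was called with an out-of-range parameter."""


@dataclasses.dataclass(frozen=True)
class GrayImage:
    """One grayscale fluorescence channel.

    Parameters
    ----------
    pixels : ndarray of float, shape (H, W)
        Non-negative intensities; processing images live on a [0, 1]
        scale.
    pixel_pitch_um : float
        Microns per pixel side. The default is the post-reduction pitch
        of a 4x stitched montage.
    """

    pixels: np.ndarray
    pixel_pitch_um: float = DEFAULT_PITCH_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if not np.issubdtype(px.dtype, np.floating):
            px = px.astype(np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ParameterError("GrayImage requires a non-empty 2-D array")
        if not np.isfinite(px).all():
            raise ParameterError("GrayImage intensities must be finite")
        if float(self.pixel_pitch_um) <= 0:
            raise ParameterError("pixel_pitch_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def pixel_area_um2(self) -> float:
        """Physical area of one pixel in square microns (pitch squared)."""
        return float(self.pixel_pitch_um) ** 2

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        return GrayImage(pixels, self.pixel_pitch_um)


@dataclasses.dataclass(frozen=True)
class BinaryMask:
    """A {0, 1} foreground/background partition of an image."""

    pixels: np.ndarray
    pixel_pitch_um: float = DEFAULT_PITCH_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ParameterError("BinaryMask requires a non-empty 2-D array")
        if px.dtype != bool:
            vals = np.unique(px)
            if not np.isin(vals, (0, 1)).all():
                raise ParameterError("BinaryMask values must be exactly 0 or 1")
            px = px.astype(bool)
        if float(self.pixel_pitch_um) <= 0:
            raise ParameterError("pixel_pitch_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclasses.dataclass(frozen=True)
class LabelMap:
    """Integer-labeled partition of foreground pixels into objects.

    Positive labels are exactly ``1..n_labels`` with no gaps; 0 is
    background. Each label's pixel set is connected under
    8-connectivity.
    """

    pixels: np.ndarray
    pixel_pitch_um: float = DEFAULT_PITCH_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ParameterError("LabelMap requires a non-empty 2-D array")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(px == np.round(px)):
                raise ParameterError("LabelMap values must be integers")
        px = px.astype(np.int32)
        if px.min() < 0:
            raise ParameterError("LabelMap values must be non-negative")
        labels = np.unique(px)
        labels = labels[labels > 0]
        if labels.size and labels[-1] != labels.size:
            raise ParameterError("LabelMap labels must be contiguous 1..n")
        object.__setattr__(self, "pixels", px)

    @property
    def n_labels(self) -> int:
        return int(self.pixels.max())

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def areas(self) -> np.ndarray:
        """Pixel area of each label, index ``i`` -> label ``i + 1``."""
        return np.bincount(self.pixels.ravel(), minlength=self.n_labels + 1)[1:]


def relabel_sequential_map(labels: np.ndarray) -> np.ndarray:
    """Remap arbitrary non-negative labels onto contiguous 1..n."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, present.size + 1, dtype=np.int32)
    return lut[labels]


# ---------------------------------------------------------------------------
# Filtering

def tophat_filter(
    img: GrayImage, radius_px: int, decomposition: str | None = None
) -> GrayImage:
    """White top-hat: image minus its opening by a disk.

    Removes background structure wider than the disk (uneven
    illumination, lens vignetting) while retaining compact bright
    features such as nuclei and colonies. Output is non-negative and
    pointwise <= the input.

    ``decomposition="sequence"`` opens with skimage's decomposed
    near-disk footprint, which is much faster for large radii at the
    price of a slightly octagonal element; the default is the exact
    Euclidean disk.
    """
    if int(radius_px) < 1:
        raise ParameterError(f"tophat radius must be >= 1 px, got {radius_px}")
    footprint = morphology.disk(int(radius_px), decomposition=decomposition)
    out = morphology.white_tophat(img.pixels, footprint=footprint)
    # grayscale opening never exceeds the image, but guard against float dust
    return img.with_pixels(np.maximum(out, 0.0))


def gaussian_smooth(img: GrayImage, sigma_px: float) -> GrayImage:
    """Convolve with a normalized Gaussian kernel (reflect padding).

    ``sigma_px == 0`` is the identity. Used to round off jagged
    binarization boundaries and to merge per-cell blobs into solid
    colony regions.
    """
    if sigma_px < 0:
        raise ParameterError(f"gaussian sigma must be >= 0, got {sigma_px}")
    if sigma_px == 0:
        return img.with_pixels(img.pixels.copy())
    out = ndi.gaussian_filter(img.pixels, sigma=float(sigma_px), mode="reflect")
    return img.with_pixels(out)


def contrast_adjust(img: GrayImage, low_pct: float, high_pct: float) -> GrayImage:
    """Linear stretch mapping the given intensity percentiles to [0, 1].

    Values below/above the percentile anchors are clipped. A degenerate
    span (equal percentile values, e.g. a constant image) yields an
    all-zero image with a warning.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ParameterError(
            f"percentiles must satisfy 0 <= low < high <= 100, got ({low_pct}, {high_pct})"
        )
    lo, hi = np.percentile(img.pixels, [low_pct, high_pct])
    if hi <= lo:
        warnings.warn(
            "degenerate percentile span in contrast_adjust; returning zeros",
            stacklevel=2,
        )
        return img.with_pixels(np.zeros_like(img.pixels))
    out = np.clip((img.pixels - lo) / (hi - lo), 0.0, 1.0)
    return img.with_pixels(out)


def binarize(
    img: GrayImage,
    method: str = "otsu",
    fixed_threshold: float = 0.5,
) -> BinaryMask:
    """Threshold an image into a foreground mask (``pixel > threshold``).

    ``method="otsu"`` derives the threshold from the image histogram;
    ``method="fixed"`` uses ``fixed_threshold`` on the contrast-adjusted
    [0, 1] scale. An all-equal image under Otsu has no histogram
    structure and yields an all-zero mask with a warning.
    """
    px = img.pixels
    if method == "fixed":
        if not (0.0 <= fixed_threshold <= 1.0):
            raise ParameterError(
                f"fixed threshold must lie in [0, 1], got {fixed_threshold}"
            )
        thr = float(fixed_threshold)
    elif method == "otsu":
        if px.max() == px.min():
            warnings.warn(
                "all-equal image has no Otsu threshold; returning empty mask",
                stacklevel=2,
            )
            return BinaryMask(np.zeros(px.shape, dtype=bool), img.pixel_pitch_um)
        thr = float(threshold_otsu(px))
    else:
        raise ParameterError(f"unknown binarization method {method!r}")
    return BinaryMask(px > thr, img.pixel_pitch_um)


# ---------------------------------------------------------------------------
# Distance transform and morphological reconstruction

def distance_transform(mask: BinaryMask) -> GrayImage:
    """Euclidean distance of each foreground pixel to the nearest
    background pixel; background maps to 0."""
    dist = ndi.distance_transform_edt(mask.pixels)
    return GrayImage(dist, mask.pixel_pitch_um)


def hminima_suppress(img: GrayImage, h: float) -> GrayImage:
    """Fill every regional minimum shallower than ``h``.

    Implemented as morphological reconstruction by erosion of
    ``img + h`` under ``img``. The output is >= the input pointwise,
    idempotent at fixed ``h``, and its regional-minimum count is
    non-increasing in ``h``. Applied to the inverted distance transform
    before watershed to prevent over-segmentation from spurious shallow
    basins.
    """
    if h < 0:
        raise ParameterError(f"h must be >= 0, got {h}")
    if h == 0:
        return img.with_pixels(img.pixels.copy())
    rec = morphology.reconstruction(
        img.pixels + h, img.pixels, method="erosion", footprint=_EXTREMA_FOOTPRINT
    )
    return img.with_pixels(rec)


def extended_maxima(img: GrayImage, h: float) -> BinaryMask:
    """Regional maxima of the h-maxima transform: maxima standing at
    least ``h`` above their surroundings.

    Used in the in vivo pipeline to find the dense cores of metastatic
    lesions in a strongly blurred intensity image, which then seed the
    watershed. By the strict-plateau convention a constant image has no
    maxima. The result is invariant to adding a constant to the image.
    """
    if h <= 0:
        raise ParameterError(f"h must be > 0, got {h}")
    px = img.pixels
    if px.max() == px.min():
        return BinaryMask(np.zeros(px.shape, dtype=bool), img.pixel_pitch_um)
    mask = morphology.h_maxima(px, h, footprint=_EXTREMA_FOOTPRINT)
    return BinaryMask(mask.astype(bool), img.pixel_pitch_um)


def regional_minima(img: GrayImage) -> BinaryMask:
    """Strict regional minima under 8-connectivity (constant image: none)."""
    px = img.pixels
    if px.max() == px.min():
        return BinaryMask(np.zeros(px.shape, dtype=bool), img.pixel_pitch_um)
    mins = morphology.local_minima(px, footprint=_EXTREMA_FOOTPRINT)
    return BinaryMask(mins.astype(bool), img.pixel_pitch_um)


# ---------------------------------------------------------------------------
# Watershed

def watershed_segment(
    relief: GrayImage,
    domain: BinaryMask,
    markers: LabelMap | None = None,
) -> LabelMap:
    """Watershed of ``relief`` restricted to ``domain``.

    The relief is treated as topography; flooding starts from
    ``markers`` if given, otherwise from every regional minimum of the
    relief inside the domain (one label per minimum). Every foreground
    pixel ends up in exactly one catchment basin; background stays 0.
    Ties at equidistant ridge pixels are broken deterministically by the
    flooding order of skimage's priority-queue watershed (lowest label
    first), so basin boundaries carry a +/- 1 px convention.
    """
    if relief.pixels.shape != domain.pixels.shape:
        raise ParameterError("relief and domain must share shape")
    dom = domain.pixels
    if not dom.any():
        return LabelMap(np.zeros(dom.shape, dtype=np.int32), domain.pixel_pitch_um)
    if markers is None:
        # raise the outside so minima cannot straddle the domain boundary
        filled = np.where(dom, relief.pixels, relief.pixels.max() + 1.0)
        seed_mask = morphology.local_minima(filled, footprint=_EXTREMA_FOOTPRINT)
        seed_mask &= dom
        marker_arr, _ = ndi.label(seed_mask, structure=_EXTREMA_FOOTPRINT)
    else:
        if markers.pixels.shape != dom.shape:
            raise ParameterError("markers must share shape with domain")
        marker_arr = markers.pixels
    labels = segmentation.watershed(
        relief.pixels, markers=marker_arr, mask=dom, connectivity=1
    )
    unassigned = dom & (labels == 0)
    if unassigned.any():
        if labels.any():
            # domain pixels only diagonally connected to any basin: adopt
            # the nearest basin's label so labels still partition the domain
            _, (ir, ic) = ndi.distance_transform_edt(labels == 0, return_indices=True)
            labels = np.where(unassigned, labels[ir, ic], labels)
        else:  # no strict minima anywhere: one basin per connected component
            labels, _ = ndi.label(dom, structure=_EXTREMA_FOOTPRINT)
    return LabelMap(relabel_sequential_map(labels), domain.pixel_pitch_um)
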