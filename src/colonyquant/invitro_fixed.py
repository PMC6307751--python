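"""Fixed-and-stained well-plate pipeline.

Colonies are segmented from the nuclear-stain (DAPI) channel: the
preprocessed binary mask is distance-transformed, the transform is
inverted with the background raised to saturation so colony centers
become catchment basins, shallow basins are removed with an h-minima
transform, and a watershed assigns every foreground pixel to a colony.
Individual nuclei are segmented with the same chain at nucleus-scale
parameters. Colonies are classified as DsRed+/GFP+ from the binarized
reporter channels, and per-nucleus Ki-67 positivity is scored as the
fraction of nuclear area overlapping the binarized CY5 stain (positive
when strictly above the 0.25 threshold). The per-colony `Ki-67 index`
is the fraction of constituent cells scored positive.

Known limitation: sheet-like areas or colonies fused into a
"super-colony" cannot be split into their original colonies; they are
reported as single objects.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from . import imgops
from .config import PipelineConfig, PreprocessParams
from .imgops import BinaryMask, GrayImage, LabelMap, ParameterError
from .io import InputError

FLUOR_CLASSES = ("DsRed+", "GFP+", "double", "none")


@dataclass
class NucleusRecord:
    nucleus_id: int
    colony_id: int  # 0 when the centroid lies on colony background
    area_px: int
    centroid: tuple[float, float]  # (row, col)
    ki67_overlap_fraction: float | None = None
    ki67_positive: bool | None = None


@dataclass
class ColonyRecord:
    colony_id: int
    area_px: int
    area_um2: float
    cell_count: int
    centroid: tuple[float, float]
    fluor_class: str = "none"
    ki67_positive_cells: int | None = None
    ki67_index: float | None = None


@dataclass
class FixedWellResult:
    colonies: list[ColonyRecord]
    nuclei: list[NucleusRecord]
    colony_labels: LabelMap
    nucleus_labels: LabelMap
    config: dict

    def colonies_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(c) for c in self.colonies])

    def nuclei_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(n) for n in self.nuclei])


# ---------------------------------------------------------------------------

def binarize_with_floor(smooth: GrayImage, params: PreprocessParams) -> BinaryMask:
    """Contrast stretch and binarize with a noise floor on the threshold.

    The stretch maps the configured percentiles of the smoothed image to
    [0, 1] and the threshold is applied on that scale, but it is never
    allowed below ``median + min_signal_snr * sigma`` of the image
    (sigma estimated robustly via the MAD). On a signal-free channel the
    percentile anchors collapse into the noise distribution and a plain
    stretch would binarize noise; the floor returns an empty mask
    instead, while genuinely sparse signal (a handful of cells in a
    whole montage) stays above it and is still detected.
    """
    px = smooth.pixels
    lo, hi = np.percentile(px, [params.contrast_low_pct, params.contrast_high_pct])
    if hi <= lo:
        warnings.warn("degenerate contrast span; returning empty mask", stacklevel=2)
        return BinaryMask(np.zeros(px.shape, dtype=bool), smooth.pixel_pitch_um)
    if params.binarize_method == "otsu":
        adj = imgops.contrast_adjust(
            smooth, params.contrast_low_pct, params.contrast_high_pct
        )
        base = lo + float(threshold_otsu(adj.pixels)) * (hi - lo)
    else:
        base = lo + float(params.binarize_threshold) * (hi - lo)
    med = float(np.median(px))
    sigma = 1.4826 * float(np.median(np.abs(px - med)))
    thr = max(base, med + params.min_signal_snr * sigma)
    return BinaryMask(px > thr, smooth.pixel_pitch_um)


def preprocess_channel(img: GrayImage, params: PreprocessParams) -> BinaryMask:
    """Top-hat -> Gaussian smooth -> contrast stretch -> binarize (with
    the noise-floor threshold of :func:`binarize_with_floor`)."""
    radius = params.tophat_radius_px(img.pixel_pitch_um)
    top = imgops.tophat_filter(img, radius, decomposition=params.tophat_decomposition)
    smooth = imgops.gaussian_smooth(top, params.sigma_px)
    return binarize_with_floor(smooth, params)


def _filter_small(labels: np.ndarray, min_area: float) -> np.ndarray:
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < min_area)
    out = labels.copy()
    out[np.isin(out, small[small > 0])] = 0
    return imgops.relabel_sequential_map(out)


def _watershed_on_distance(mask: BinaryMask, h: float, min_area: float) -> LabelMap:
    """Shared colony/nucleus chain: EDT -> invert (background raised to
    saturation) -> h-minima -> watershed -> area filter."""
    if not mask.pixels.any():
        return LabelMap(np.zeros(mask.pixels.shape, np.int32), mask.pixel_pitch_um)
    dist = imgops.distance_transform(mask)
    top = float(dist.pixels.max())
    relief = np.where(mask.pixels, top - dist.pixels, top + 1.0)
    relief_img = imgops.hminima_suppress(GrayImage(relief, mask.pixel_pitch_um), h)
    labels = imgops.watershed_segment(relief_img, mask)
    return LabelMap(_filter_small(labels.pixels, min_area), mask.pixel_pitch_um)


def segment_colonies(dapi_mask: BinaryMask, cfg: PipelineConfig) -> LabelMap:
    """Watershed colonies from the preprocessed nuclear-channel mask;
    objects below the minimum colony area are discarded."""
    return _watershed_on_distance(dapi_mask, cfg.h_colony_px, cfg.min_colony_area_px)


def segment_nuclei(dapi_img: GrayImage, cfg: PipelineConfig) -> LabelMap:
    """Segment individual nuclei from the raw nuclear channel with
    nucleus-scale preprocessing and watershed parameters."""
    mask = preprocess_channel(dapi_img, cfg.nucleus_pre)
    return _watershed_on_distance(mask, cfg.h_nucleus_px, cfg.min_nucleus_area_px)


def _centroids(labels: LabelMap) -> np.ndarray:
    """(n_labels, 2) array of (row, col) centroids, index i -> label i+1."""
    n = labels.n_labels
    if n == 0:
        return np.empty((0, 2))
    return np.asarray(ndi.center_of_mass(np.ones_like(labels.pixels), labels.pixels, np.arange(1, n + 1)))


def assign_nuclei_to_colonies(colony_labels: LabelMap, nucleus_labels: LabelMap) -> np.ndarray:
    """Colony id of each nucleus (index i -> nucleus label i+1), by the
    colony label under the nucleus centroid; 0 when on background."""
    if colony_labels.pixels.shape != nucleus_labels.pixels.shape:
        raise ParameterError("colony and nucleus label maps must share shape")
    cents = _centroids(nucleus_labels)
    if cents.size == 0:
        return np.empty(0, dtype=np.int32)
    rows = np.clip(np.rint(cents[:, 0]).astype(int), 0, colony_labels.height - 1)
    cols = np.clip(np.rint(cents[:, 1]).astype(int), 0, colony_labels.width - 1)
    return colony_labels.pixels[rows, cols].astype(np.int32)


def count_cells_per_colony(
    colony_labels: LabelMap, nucleus_labels: LabelMap
) -> dict[int, int]:
    """Number of nuclei whose centroid falls inside each colony."""
    assignment = assign_nuclei_to_colonies(colony_labels, nucleus_labels)
    counts = np.bincount(assignment, minlength=colony_labels.n_labels + 1)
    return {cid: int(counts[cid]) for cid in range(1, colony_labels.n_labels + 1)}


def classify_colonies(
    colony_labels: LabelMap,
    gfp_mask: BinaryMask | None,
    rfp_mask: BinaryMask | None,
    cfg: PipelineConfig,
) -> dict[int, str]:
    """Assign DsRed+/GFP+/double/none by the fraction of colony pixels
    overlapping each binarized reporter mask."""
    n = colony_labels.n_labels
    areas = colony_labels.areas().astype(float)
    idx = np.arange(1, n + 1)

    def _frac(mask: BinaryMask | None) -> np.ndarray:
        if mask is None or n == 0:
            return np.zeros(n)
        inter = ndi.sum_labels(mask.pixels.astype(float), colony_labels.pixels, idx)
        return inter / areas

    gfrac, rfrac = _frac(gfp_mask), _frac(rfp_mask)
    out: dict[int, str] = {}
    for i, cid in enumerate(idx):
        g = gfrac[i] >= cfg.class_min_fraction
        r = rfrac[i] >= cfg.class_min_fraction
        out[int(cid)] = "double" if (g and r) else "GFP+" if g else "DsRed+" if r else "none"
    return out


def ki67_score(
    nucleus_labels: LabelMap,
    ki67_mask: BinaryMask,
    threshold: float = 0.25,
) -> list[NucleusRecord]:
    """Score each nucleus against the binarized Ki-67 (CY5) stain.

    The overlap fraction is the share of nuclear pixels inside the
    stain mask; a nucleus is positive only when the fraction is
    strictly greater than ``threshold``.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ParameterError(f"ki67 threshold must lie in [0, 1], got {threshold}")
    if nucleus_labels.pixels.shape != ki67_mask.pixels.shape:
        raise ParameterError("nucleus labels and Ki-67 mask must share shape")
    n = nucleus_labels.n_labels
    areas = nucleus_labels.areas()
    cents = _centroids(nucleus_labels)
    idx = np.arange(1, n + 1)
    inter = (
        ndi.sum_labels(ki67_mask.pixels.astype(float), nucleus_labels.pixels, idx)
        if n
        else np.empty(0)
    )
    records = []
    for i in range(n):
        frac = float(inter[i]) / float(areas[i])
        records.append(
            NucleusRecord(
                nucleus_id=i + 1,
                colony_id=0,
                area_px=int(areas[i]),
                centroid=(float(cents[i, 0]), float(cents[i, 1])),
                ki67_overlap_fraction=frac,
                ki67_positive=bool(frac > threshold),
            )
        )
    return records


def build_fixed_result(
    channels: dict[str, GrayImage],
    cfg: PipelineConfig | None = None,
) -> FixedWellResult:
    """Run the full fixed-cell pipeline on a channel dictionary.

    ``channels`` maps tags to images; ``"dapi"`` is required, the
    reporter channels ``"gfp"``/``"rfp"`` and the Ki-67 stain ``"cy5"``
    are optional (classification / Ki-67 scoring are skipped when
    absent).
    """
    cfg = cfg or PipelineConfig()
    if "dapi" not in channels:
        raise InputError("fixed-cell pipeline requires a DAPI channel")
    dapi = channels["dapi"]

    colony_mask = preprocess_channel(dapi, cfg.colony_pre)
    colony_labels = segment_colonies(colony_mask, cfg)
    nucleus_labels = segment_nuclei(dapi, cfg)

    gfp_mask = (
        preprocess_channel(channels["gfp"], cfg.colony_pre) if "gfp" in channels else None
    )
    rfp_mask = (
        preprocess_channel(channels["rfp"], cfg.colony_pre) if "rfp" in channels else None
    )
    classes = classify_colonies(colony_labels, gfp_mask, rfp_mask, cfg)

    if "cy5" in channels:
        ki67_mask = preprocess_channel(channels["cy5"], cfg.nucleus_pre)
        nuclei = ki67_score(nucleus_labels, ki67_mask, cfg.ki67_threshold)
    else:
        areas = nucleus_labels.areas()
        cents = _centroids(nucleus_labels)
        nuclei = [
            NucleusRecord(i + 1, 0, int(areas[i]), (float(cents[i, 0]), float(cents[i, 1])))
            for i in range(nucleus_labels.n_labels)
        ]

    assignment = assign_nuclei_to_colonies(colony_labels, nucleus_labels)
    for rec, cid in zip(nuclei, assignment):
        rec.colony_id = int(cid)

    colony_areas = colony_labels.areas()
    colony_cents = _centroids(colony_labels)
    pitch2 = colony_labels.pixel_pitch_um**2
    colonies = []
    for cid in range(1, colony_labels.n_labels + 1):
        members = [r for r in nuclei if r.colony_id == cid]
        rec = ColonyRecord(
            colony_id=cid,
            area_px=int(colony_areas[cid - 1]),
            area_um2=float(colony_areas[cid - 1]) * pitch2,
            cell_count=len(members),
            centroid=(float(colony_cents[cid - 1, 0]), float(colony_cents[cid - 1, 1])),
            fluor_class=classes[cid],
        )
        if "cy5" in channels and members:
            pos = sum(1 for r in members if r.ki67_positive)
            rec.ki67_positive_cells = pos
            rec.ki67_index = pos / len(members)
        colonies.append(rec)

    return FixedWellResult(
        colonies=colonies,
        nuclei=nuclei,
        colony_labels=colony_labels,
        nucleus_labels=nucleus_labels,
        config=cfg.to_dict(),
    )
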