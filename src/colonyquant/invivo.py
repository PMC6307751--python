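"""Two-part lung-section pipeline for metastatic colony quantification.

Part 1 (macrometastases): the reporter channel, restricted to the lung
tissue mask, is top-hat filtered and then blurred strongly enough that
lesions of only a few cells vanish; the extended-maximum transform of
the blurred image marks the dense cores of the remaining large lesions,
which seed a watershed that splits even adjacent lesions that a plain
binarization would merge. The distance-transform seeding of the
in vitro mode is not used here: lung tissue is too variable for it.

Part 2 (micrometastases): macro lesions are masked out and the
remaining area is scanned with light preprocessing for connected
components a few cells in size. Any candidate whose boundary lies
within the exclusion distance (default 40 px) of a macro lesion is
flagged and not counted, since it cannot be distinguished from cells
migrating out of the neighboring colony; candidates outside the lung
are likewise flagged.

The DAPI channel only delineates lung tissue from background and plays
no role in the colony segmentation itself.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology

from . import imgops
from .config import PipelineConfig
from .imgops import BinaryMask, GrayImage, LabelMap
from .invitro_fixed import _centroids, binarize_with_floor
from .io import InputError

_S8 = np.ones((3, 3), dtype=bool)


@dataclass
class MetastasisRecord:
    lesion_id: int
    kind: str  # "macro" | "micro"
    channel: str  # "GFP" | "RFP"
    area_px: int
    area_um2: float
    centroid: tuple[float, float]
    estimated_cell_count: float | None = None  # micro only (area / cell area)
    excluded: bool = False
    exclusion_reason: str = "none"  # "near_macro" | "outside_lung" | "none"
    distance_to_macro_px: float | None = None


@dataclass
class LungSectionResult:
    lung_mask: BinaryMask
    macro_labels: dict[str, LabelMap]
    micro_labels: dict[str, LabelMap]
    records: list[MetastasisRecord]
    config: dict

    def records_frame(self) -> pd.DataFrame:
        cols = [f.name for f in dataclasses.fields(MetastasisRecord)]
        return pd.DataFrame(
            [dataclasses.asdict(r) for r in self.records], columns=cols
        )

    def counted(self, channel: str | None = None) -> list[MetastasisRecord]:
        return [
            r
            for r in self.records
            if not r.excluded and (channel is None or r.channel == channel)
        ]

    def sizes(self, channel: str | None = None) -> np.ndarray:
        return np.asarray([r.area_px for r in self.counted(channel)], dtype=float)


# ---------------------------------------------------------------------------

def lung_mask(dapi_img: GrayImage, cfg: PipelineConfig | None = None) -> BinaryMask:
    """Tissue mask from the DAPI channel: heavy blur, Otsu threshold,
    morphological closing, largest connected component, hole filling."""
    cfg = cfg or PipelineConfig()
    px = dapi_img.pixels
    if px.max() == px.min():
        warnings.warn("blank DAPI image; lung mask is empty", stacklevel=2)
        return BinaryMask(np.zeros(px.shape, bool), dapi_img.pixel_pitch_um)
    blurred = imgops.gaussian_smooth(dapi_img, cfg.lung_blur_sigma_px)
    rough = imgops.binarize(blurred, method="otsu").pixels
    rough = morphology.closing(rough, morphology.disk(cfg.lung_close_radius_px))
    labels, n = ndi.label(rough, structure=_S8)
    if n == 0:
        warnings.warn("no tissue found in DAPI image", stacklevel=2)
        return BinaryMask(np.zeros(px.shape, bool), dapi_img.pixel_pitch_um)
    largest = int(np.argmax(np.bincount(labels.ravel())[1:])) + 1
    mask = ndi.binary_fill_holes(labels == largest)
    return BinaryMask(mask, dapi_img.pixel_pitch_um)


def segment_macro(
    channel_img: GrayImage, lung: BinaryMask, cfg: PipelineConfig | None = None
) -> LabelMap:
    """Part 1: extended-maximum-seeded watershed of large lesions.

    The contrast stretch of the blurred image is anchored to a high
    percentile of the *pre-blur* top-hat image inside the lung, so that
    the attenuation introduced by the blur is preserved on the stretched
    scale and sections containing nothing but micrometastases produce no
    macro labels. The watershed domain is the blurred macro mask unioned
    with the sharp-foreground components overlapping it, so reported
    lesion extents follow the true (unblurred) lesion boundary — the
    boundary the exclusion rule of Part 2 measures from.
    """
    cfg = cfg or PipelineConfig()
    pitch = channel_img.pixel_pitch_um
    if not lung.pixels.any():
        return LabelMap(np.zeros(lung.pixels.shape, np.int32), pitch)
    # top-hat the unrestricted channel (masking first would leave an
    # artificial background ring along the lung boundary), restrict to
    # the lung in every downstream mask
    radius = max(1, round(cfg.vivo_tophat_radius_um / pitch))
    top = imgops.tophat_filter(
        channel_img, radius, decomposition=cfg.vivo_micro_pre.tophat_decomposition
    )
    blur = imgops.gaussian_smooth(top, cfg.macro_blur_sigma_px)

    # anchored stretch: scale set before blurring, floor set after
    hi = float(np.percentile(top.pixels[lung.pixels], 99.9))
    lo = float(np.percentile(blur.pixels[lung.pixels], 1.0))
    med = float(np.median(top.pixels[lung.pixels]))
    noise = 1.4826 * float(np.median(np.abs(top.pixels[lung.pixels] - med)))
    if hi <= lo or (hi - lo) < cfg.vivo_micro_pre.min_signal_snr * noise:
        # signal-free channel: nothing to segment
        return LabelMap(np.zeros(lung.pixels.shape, np.int32), pitch)
    adj = GrayImage(np.clip((blur.pixels - lo) / (hi - lo), 0.0, 1.0), pitch)

    blurred_mask = (adj.pixels > cfg.vivo_binarize_threshold) & lung.pixels
    if not blurred_mask.any():
        return LabelMap(np.zeros(lung.pixels.shape, np.int32), pitch)
    seeds = imgops.extended_maxima(adj, cfg.h_vivo).pixels & blurred_mask
    if not seeds.any():
        return LabelMap(np.zeros(lung.pixels.shape, np.int32), pitch)
    markers, _ = ndi.label(seeds, structure=_S8)

    # refine extent with the sharp (unblurred) foreground of the same
    # top-hat image, binarized on the same anchored scale
    sharp_img = imgops.gaussian_smooth(top, cfg.vivo_micro_pre.sigma_px)
    sharp = (
        np.clip((sharp_img.pixels - lo) / (hi - lo), 0.0, 1.0)
        > cfg.vivo_binarize_threshold
    ) & lung.pixels
    sharp_lab, n_sharp = ndi.label(sharp, structure=_S8)
    if n_sharp:
        overlapping = np.unique(sharp_lab[blurred_mask & (sharp_lab > 0)])
        domain = blurred_mask | np.isin(sharp_lab, overlapping[overlapping > 0])
    else:
        domain = blurred_mask
    relief = GrayImage(adj.pixels.max() - adj.pixels, pitch)
    labels = imgops.watershed_segment(
        relief, BinaryMask(domain, pitch), LabelMap(imgops.relabel_sequential_map(markers), pitch)
    )
    from .invitro_fixed import _filter_small

    return LabelMap(_filter_small(labels.pixels, cfg.macro_min_area_px), pitch)


def scan_micro(
    channel_img: GrayImage,
    macro: LabelMap,
    lung: BinaryMask,
    cfg: PipelineConfig | None = None,
) -> tuple[LabelMap, list[MetastasisRecord]]:
    """Part 2: scan the macro-masked remainder for micrometastases.

    Candidate components found by the light preprocessing chain are
    refined to their half-peak (FWHM) footprint before the size window
    and the boundary-distance measurement are applied; the half-peak
    contour of a compact blob is insensitive to the global contrast
    stretch, which keeps the exclusion distance accurate to about a
    pixel. Returns the candidate label map together with per-lesion
    records carrying exclusion flags; excluded lesions stay in the
    label map but must not enter counts or size distributions.
    """
    cfg = cfg or PipelineConfig()
    pre = cfg.vivo_micro_pre
    pitch = channel_img.pixel_pitch_um
    px = np.where(macro.pixels > 0, 0.0, channel_img.pixels)
    img = GrayImage(px, pitch)
    top = imgops.tophat_filter(
        img, pre.tophat_radius_px(pitch), decomposition=pre.tophat_decomposition
    )
    smooth = imgops.gaussian_smooth(top, pre.sigma_px)
    mask = binarize_with_floor(smooth, pre).pixels
    if cfg.micro_close_radius_px > 0:
        # join the cells of one sparse seeding event into one candidate
        mask = morphology.closing(mask, morphology.disk(cfg.micro_close_radius_px))
    mask &= macro.pixels == 0

    comp, n = ndi.label(mask, structure=_S8)
    refined = np.zeros_like(comp)
    if n:
        # half-peak (FWHM) refinement per component on the unsmoothed
        # top-hat image: the half-maximum contour of a compact blob is
        # insensitive to both the contrast stretch and the smoothing
        # kernel; one candidate per component even if the refined
        # pixels disconnect
        peaks = ndi.maximum(top.pixels, comp, np.arange(1, n + 1))
        half = np.concatenate([[np.inf], np.asarray(peaks, dtype=float) / 2.0])
        refined = np.where(top.pixels >= half[comp], comp, 0)
        areas_r = np.bincount(refined.ravel(), minlength=n + 1)
        keep = (areas_r >= cfg.micro_min_area_px) & (areas_r <= cfg.micro_max_area_px)
        keep[0] = False
        comp = np.where(keep[comp], comp, 0)
        refined = np.where(keep[refined], refined, 0)
    # shared relabeling for the component map and its refined support
    old = np.unique(comp)
    old = old[old > 0]
    lut = np.zeros(n + 1, dtype=np.int32)
    lut[old] = np.arange(1, old.size + 1, dtype=np.int32)
    labels = LabelMap(lut[comp], pitch)
    refined = lut[refined]

    if macro.n_labels > 0:
        dist_to_macro = ndi.distance_transform_edt(macro.pixels == 0)
    else:
        dist_to_macro = np.full(mask.shape, np.inf)

    records: list[MetastasisRecord] = []
    for i in range(labels.n_labels):
        sel = refined == i + 1
        area = int(sel.sum())
        d = float(dist_to_macro[sel].min())
        cr, cc = ndi.center_of_mass(sel)
        r = int(np.clip(round(cr), 0, lung.height - 1))
        c = int(np.clip(round(cc), 0, lung.width - 1))
        reason = "none"
        if d <= cfg.exclusion_px:
            reason = "near_macro"
        elif not lung.pixels[r, c]:
            reason = "outside_lung"
        records.append(
            MetastasisRecord(
                lesion_id=i + 1,
                kind="micro",
                channel="",
                area_px=area,
                area_um2=area * pitch**2,
                centroid=(float(cr), float(cc)),
                estimated_cell_count=area / cfg.cell_area_px,
                excluded=reason != "none",
                exclusion_reason=reason,
                distance_to_macro_px=None if np.isinf(d) else d,
            )
        )
    return labels, records


def analyze_section(
    channels: dict[str, GrayImage], cfg: PipelineConfig | None = None
) -> LungSectionResult:
    """Run both parts on a section: DAPI plus at least one reporter
    channel ("gfp" and/or "rfp")."""
    cfg = cfg or PipelineConfig()
    if "dapi" not in channels:
        raise InputError("in vivo pipeline requires a DAPI channel")
    reporters = [t for t in ("gfp", "rfp") if t in channels]
    if not reporters:
        raise InputError("in vivo pipeline requires a GFP and/or RFP channel")

    lung = lung_mask(channels["dapi"], cfg)
    macro_labels: dict[str, LabelMap] = {}
    micro_labels: dict[str, LabelMap] = {}
    records: list[MetastasisRecord] = []
    for tag in reporters:
        chan_name = tag.upper()
        img = channels[tag]
        macro = segment_macro(img, lung, cfg)
        macro_labels[tag] = macro
        areas = macro.areas()
        cents = _centroids(macro)
        for i in range(macro.n_labels):
            records.append(
                MetastasisRecord(
                    lesion_id=i + 1,
                    kind="macro",
                    channel=chan_name,
                    area_px=int(areas[i]),
                    area_um2=float(areas[i]) * img.pixel_pitch_um**2,
                    centroid=(float(cents[i, 0]), float(cents[i, 1])),
                )
            )
        micro, micro_recs = scan_micro(img, macro, lung, cfg)
        micro_labels[tag] = micro
        for rec in micro_recs:
            rec.channel = chan_name
        records.extend(micro_recs)

    return LungSectionResult(
        lung_mask=lung,
        macro_labels=macro_labels,
        micro_labels=micro_labels,
        records=records,
        config=cfg.to_dict(),
    )
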