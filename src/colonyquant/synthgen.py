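"""Ground-truth synthetic image generator.

Emulates 4x-magnification stitched fluorescence montages: roughly
circular colonies made of Gaussian-blob "cells" on a noisy background
with a low-frequency illumination gradient (which exercises the top-hat
correction), at the post-reduction pixel pitch of 2.692 um. Three
scenes are produced — fixed-and-stained wells (DAPI/GFP/RFP/CY5), live
wells (GFP/RFP over timepoints with monotone colony growth), and
two-lobe lung tissue sections with macro- and micrometastases placed at
controlled distances to exercise the exclusion rule.

The generator is the primary test oracle: every rendered object is
recorded in a :class:`SyntheticGroundTruth` table (class, center, cell
count, cell positions, footprint mask). Truth footprints are defined as
the pixels where the noiseless rendered signal reaches half of the blob
amplitude, so they are consistent with what a half-maximum binarization
of the rendered image recovers. Identical seed and parameters yield
bit-identical output.

The generator is deliberately not photorealistic (no PSF or stitching
artifacts); its job is to provide exact ground truth under the imaging
regime the pipelines are designed for.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imgops import DEFAULT_PITCH_UM, GrayImage, LabelMap, ParameterError
from .io import write_channel_tiff

_S8 = np.ones((3, 3), dtype=bool)

#: a Gaussian blob of width sigma falls to half its peak at r = sigma * HALF_MAX_R
HALF_MAX_R = math.sqrt(2.0 * math.log(2.0))


class PlacementError(RuntimeError):
    """Requested object density could not be placed within bounded retries."""


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic imaging regime."""

    # geometry
    height: int = 512
    width: int = 512
    pixel_pitch_um: float = DEFAULT_PITCH_UM
    nucleus_radius_um: float = 7.0
    #: minimum cell center spacing, in nucleus radii
    cell_spacing_factor: float = 3.5

    # well content
    n_colonies: int = 12
    min_cells_per_colony: int = 4
    #: lognormal parameters of cells per colony (median ~7 cells)
    cells_log_mean: float = 2.0
    cells_log_sd: float = 0.6
    #: minimum gap between colony footprints (px); keeps colonies non-touching
    colony_margin_px: float = 12.0
    #: fraction of colonies carrying the GFP reporter (rest DsRed)
    gfp_fraction: float = 0.5
    #: per-class probability that a nucleus is Ki-67 positive
    ki67_positive_fraction: dict = field(
        default_factory=lambda: {"DsRed+": 0.9, "GFP+": 0.5}
    )

    # rendering
    blob_amplitude: float = 0.75
    reporter_amplitude: float = 0.6
    background_level: float = 0.08
    noise_sd: float = 0.02
    vignetting_amplitude: float = 0.05

    # live mode
    #: per-timepoint colony area growth factor
    growth_factor: float = 1.5

    # lung sections
    n_macro: int = 4
    macro_radius_px: tuple = (24.0, 38.0)
    macro_amplitude: float = 0.85
    n_micro: int = 6
    micro_cells: tuple = (3, 8)
    #: boundary gap (px) of randomly placed micro clusters from any macro
    micro_gap_px: tuple = (60.0, 160.0)
    #: explicit boundary gaps from the first macro lesion; overrides n_micro
    micro_gaps_px: list | None = None
    #: place two macro lesions this close together (px gap); None disables
    adjacent_macro_gap_px: float | None = None
    lung_margin_px: float = 30.0

    def validate(self) -> None:
        if self.n_colonies < 0 or self.n_macro < 0 or self.n_micro < 0:
            raise ParameterError("object counts must be >= 0")
        fracs = [self.gfp_fraction, *self.ki67_positive_fraction.values()]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ParameterError("fractions must lie in [0, 1]")

    @property
    def nucleus_radius_px(self) -> float:
        return self.nucleus_radius_um / self.pixel_pitch_um

    @property
    def blob_sigma_px(self) -> float:
        """Blob width whose half-maximum radius equals the nucleus radius."""
        return self.nucleus_radius_px / HALF_MAX_R

    @property
    def cell_spacing_px(self) -> float:
        return self.cell_spacing_factor * self.nucleus_radius_px


@dataclass
class SyntheticGroundTruth:
    """Per-object truth for one generated scene."""

    objects: pd.DataFrame  # one row per colony / lesion
    cells: pd.DataFrame  # one row per cell (center, parent, flags)
    object_labels: LabelMap  # truth footprints, label i = object_id i
    params: dict
    seed: int

    def footprint(self, object_id: int) -> np.ndarray:
        return self.object_labels.pixels == object_id

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.objects.to_csv(directory / "truth.csv", index=False)
        self.cells.to_csv(directory / "truth_cells.csv", index=False)
        import json

        (directory / "params.json").write_text(
            json.dumps({"seed": self.seed, **self.params}, indent=2, default=str)
        )


# ---------------------------------------------------------------------------
# rendering helpers

def _field(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Background level plus a quadratic vignetting bowl."""
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    cy, cx = (cfg.height - 1) / 2.0, (cfg.width - 1) / 2.0
    r2 = ((yy - cy) / cfg.height) ** 2 + ((xx - cx) / cfg.width) ** 2
    return cfg.background_level + cfg.vignetting_amplitude * (0.5 - r2) * 2.0


def _add_blob(canvas: np.ndarray, r: float, c: float, sigma: float, amp: float) -> None:
    """Add a Gaussian blob in place (windowed to 4 sigma)."""
    h, w = canvas.shape
    half = int(math.ceil(4.0 * sigma))
    r0, r1 = max(0, int(r) - half), min(h, int(r) + half + 1)
    c0, c1 = max(0, int(c) - half), min(w, int(c) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1] += amp * np.exp(
        -((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * sigma**2)
    )


def _add_soft_disk(
    canvas: np.ndarray, r: float, c: float, radius: float, amp: float, edge: float = 1.5
) -> None:
    """Add a plateau disk with a soft (sigmoid) edge in place."""
    h, w = canvas.shape
    half = int(math.ceil(radius + 4.0 * edge))
    r0, r1 = max(0, int(r) - half), min(h, int(r) + half + 1)
    c0, c1 = max(0, int(c) - half), min(w, int(c) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dist = np.sqrt((yy - r) ** 2 + (xx - c) ** 2)
    canvas[r0:r1, c0:c1] += amp / (1.0 + np.exp((dist - radius) / edge))


def _finish(signal: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator) -> GrayImage:
    """Add illumination field and noise; clip into [0, 1]."""
    out = signal + _field(cfg, rng) + rng.normal(0.0, cfg.noise_sd, signal.shape)
    return GrayImage(np.clip(out, 0.0, 1.0), cfg.pixel_pitch_um)


def _footprint_labels(
    signals: list[np.ndarray], half_level: float, cfg: GeneratorConfig
) -> LabelMap:
    """Label map of truth footprints: object i owns the pixels where its
    own noiseless signal reaches ``half_level`` (ties -> strongest)."""
    shape = (cfg.height, cfg.width)
    best = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    for i, sig in enumerate(signals, start=1):
        sel = (sig >= half_level) & (sig > best)
        labels[sel] = i
        best[sel] = sig[sel]
    return LabelMap(labels, cfg.pixel_pitch_um)


def _place_cells(
    n: int, radius_hint: float, spacing: float, rng: np.random.Generator
) -> np.ndarray:
    """Cell centers on a jittered hexagonal packing inside a disk.

    Guarantees pairwise spacing >= ~0.86 * ``spacing`` so nuclei remain
    separable; returns offsets relative to the colony center, the ``n``
    sites closest to the center first.
    """
    rows = int(math.ceil(2.0 * radius_hint / (spacing * math.sqrt(3) / 2))) + 3
    cols = int(math.ceil(2.0 * radius_hint / spacing)) + 3
    pts = []
    for i in range(-rows, rows + 1):
        for j in range(-cols, cols + 1):
            y = i * spacing * math.sqrt(3) / 2
            x = (j + 0.5 * (i % 2)) * spacing
            pts.append((y, x))
    pts = np.asarray(pts)
    pts += rng.uniform(-0.07 * spacing, 0.07 * spacing, pts.shape)
    order = np.argsort(np.hypot(pts[:, 0], pts[:, 1]))
    return pts[order[:n]]


def _colony_radius(n_cells: int, spacing: float) -> float:
    """Approximate footprint radius of a packed colony of n cells."""
    return spacing * math.sqrt(n_cells / math.pi) + spacing * 0.7


# ---------------------------------------------------------------------------
# fixed wells

def generate_fixed_well(
    cfg: GeneratorConfig | None = None, seed: int = 0
) -> tuple[dict[str, GrayImage], SyntheticGroundTruth]:
    """Render a fixed-and-stained well: DAPI nuclei, whole-colony
    reporter footprints, and CY5 blobs at Ki-67-positive nuclei."""
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    spacing = cfg.cell_spacing_px
    sigma = cfg.blob_sigma_px

    # sample colony sizes and non-overlapping centers
    n_cells = np.maximum(
        cfg.min_cells_per_colony,
        np.round(rng.lognormal(cfg.cells_log_mean, cfg.cells_log_sd, cfg.n_colonies)),
    ).astype(int)
    radii = np.array([_colony_radius(k, spacing) for k in n_cells])
    centers = _sample_centers(
        radii + cfg.colony_margin_px / 2.0,
        cfg.height,
        cfg.width,
        rng,
        border=cfg.colony_margin_px,
    )

    classes = np.where(
        rng.random(cfg.n_colonies) < cfg.gfp_fraction, "GFP+", "DsRed+"
    )

    dapi_sig = np.zeros((cfg.height, cfg.width))
    gfp_sig = np.zeros_like(dapi_sig)
    rfp_sig = np.zeros_like(dapi_sig)
    cy5_sig = np.zeros_like(dapi_sig)
    colony_signals: list[np.ndarray] = []

    obj_rows, cell_rows = [], []
    for cid in range(cfg.n_colonies):
        cy, cx = centers[cid]
        offsets = _place_cells(n_cells[cid], radii[cid], spacing, rng)
        own = np.zeros_like(dapi_sig)
        for k, (dy, dx) in enumerate(offsets):
            r, c = cy + dy, cx + dx
            _add_blob(own, r, c, sigma, cfg.blob_amplitude)
            pos_frac = cfg.ki67_positive_fraction.get(str(classes[cid]), 0.0)
            ki67 = bool(rng.random() < pos_frac)
            if ki67:
                _add_blob(cy5_sig, r, c, sigma, cfg.blob_amplitude)
            cell_rows.append(
                {
                    "cell_id": len(cell_rows) + 1,
                    "object_id": cid + 1,
                    "row": r,
                    "col": c,
                    "ki67_positive": ki67,
                }
            )
        dapi_sig += own
        colony_signals.append(own)
        target = gfp_sig if classes[cid] == "GFP+" else rfp_sig
        _add_soft_disk(target, cy, cx, radii[cid], cfg.reporter_amplitude)
        obj_rows.append(
            {
                "object_id": cid + 1,
                "kind": "colony",
                "fluor_class": classes[cid],
                "row": cy,
                "col": cx,
                "cell_count": int(n_cells[cid]),
                "footprint_radius_px": radii[cid],
            }
        )

    labels = _footprint_labels(colony_signals, cfg.blob_amplitude / 2.0, cfg)
    areas = labels.areas() if labels.n_labels else np.empty(0, dtype=int)
    for row in obj_rows:
        row["footprint_area_px"] = int(areas[row["object_id"] - 1]) if len(areas) else 0
        row["ki67_index"] = float(
            np.mean(
                [c["ki67_positive"] for c in cell_rows if c["object_id"] == row["object_id"]]
            )
        )

    channels = {
        "dapi": _finish(dapi_sig, cfg, rng),
        "gfp": _finish(gfp_sig, cfg, rng),
        "rfp": _finish(rfp_sig, cfg, rng),
        "cy5": _finish(cy5_sig, cfg, rng),
    }
    truth = SyntheticGroundTruth(
        objects=pd.DataFrame(
            obj_rows,
            columns=[
                "object_id",
                "kind",
                "fluor_class",
                "row",
                "col",
                "cell_count",
                "footprint_radius_px",
                "footprint_area_px",
                "ki67_index",
            ],
        ),
        cells=pd.DataFrame(
            cell_rows, columns=["cell_id", "object_id", "row", "col", "ki67_positive"]
        ),
        object_labels=labels,
        params=dataclasses.asdict(cfg),
        seed=seed,
    )
    return channels, truth


def _sample_centers(
    exclusion_radii: np.ndarray,
    height: int,
    width: int,
    rng: np.random.Generator,
    border: float = 0.0,
    max_tries: int = 4000,
    region_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Rejection-sample centers so footprint disks stay inside the frame
    (or region) and never overlap each other."""
    centers: list[tuple[float, float]] = []
    for i, rad in enumerate(exclusion_radii):
        ok = False
        for _ in range(max_tries):
            r = rng.uniform(rad + border, height - rad - border)
            c = rng.uniform(rad + border, width - rad - border)
            if region_mask is not None and not region_mask[int(r), int(c)]:
                continue
            if all(
                math.hypot(r - pr, c - pc) > rad + exclusion_radii[j]
                for j, (pr, pc) in enumerate(centers)
            ):
                centers.append((r, c))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place object {i + 1}/{len(exclusion_radii)}"
            )
    return np.asarray(centers).reshape(-1, 2)


# ---------------------------------------------------------------------------
# live wells

def generate_live_well(
    cfg: GeneratorConfig | None = None, seed: int = 0, timepoints: int = 1
) -> tuple[list[dict[str, GrayImage]], list[SyntheticGroundTruth]]:
    """Render a live well over time: whole-colony reporter footprints
    whose areas grow by ``cfg.growth_factor`` per step (no nuclear or
    Ki-67 staining)."""
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    if timepoints < 1:
        raise ParameterError("timepoints must be >= 1")
    rng = np.random.default_rng(seed)
    spacing = cfg.cell_spacing_px

    n_cells = np.maximum(
        cfg.min_cells_per_colony,
        np.round(rng.lognormal(cfg.cells_log_mean, cfg.cells_log_sd, cfg.n_colonies)),
    ).astype(int)
    base_radii = np.array([_colony_radius(k, spacing) for k in n_cells])
    # leave room for the final-timepoint radius
    final_scale = math.sqrt(cfg.growth_factor ** max(0, timepoints - 1))
    centers = _sample_centers(
        base_radii * final_scale + cfg.colony_margin_px / 2.0,
        cfg.height,
        cfg.width,
        rng,
        border=cfg.colony_margin_px,
    )
    classes = np.where(rng.random(cfg.n_colonies) < cfg.gfp_fraction, "GFP+", "DsRed+")

    frames, truths = [], []
    for t in range(timepoints):
        scale = math.sqrt(cfg.growth_factor**t)
        gfp_sig = np.zeros((cfg.height, cfg.width))
        rfp_sig = np.zeros_like(gfp_sig)
        signals, rows = [], []
        for cid in range(cfg.n_colonies):
            rad = base_radii[cid] * scale
            own = np.zeros_like(gfp_sig)
            _add_soft_disk(own, centers[cid, 0], centers[cid, 1], rad, cfg.reporter_amplitude)
            signals.append(own)
            if classes[cid] == "GFP+":
                gfp_sig += own
            else:
                rfp_sig += own
            rows.append(
                {
                    "object_id": cid + 1,
                    "kind": "colony",
                    "fluor_class": classes[cid],
                    "row": centers[cid, 0],
                    "col": centers[cid, 1],
                    "cell_count": int(n_cells[cid]),
                    "footprint_radius_px": rad,
                    "timepoint": t,
                }
            )
        labels = _footprint_labels(signals, cfg.reporter_amplitude / 2.0, cfg)
        areas = labels.areas() if labels.n_labels else np.empty(0, dtype=int)
        for row in rows:
            row["footprint_area_px"] = int(areas[row["object_id"] - 1]) if len(areas) else 0
        frames.append({"gfp": _finish(gfp_sig, cfg, rng), "rfp": _finish(rfp_sig, cfg, rng)})
        truths.append(
            SyntheticGroundTruth(
                objects=pd.DataFrame(rows),
                cells=pd.DataFrame(
                    columns=["cell_id", "object_id", "row", "col", "ki67_positive"]
                ),
                object_labels=labels,
                params=dataclasses.asdict(cfg),
                seed=seed,
            )
        )
    return frames, truths


# ---------------------------------------------------------------------------
# lung sections

def _lung_shape(cfg: GeneratorConfig) -> np.ndarray:
    """Two-lobe tissue shape: a pair of overlapping ellipses."""
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    cy = cfg.height / 2.0
    ry, rx = cfg.height * 0.38, cfg.width * 0.24
    left = ((yy - cy) / ry) ** 2 + ((xx - cfg.width * 0.30) / rx) ** 2 <= 1.0
    right = ((yy - cy) / ry) ** 2 + ((xx - cfg.width * 0.68) / rx) ** 2 <= 1.0
    return left | right


def generate_lung_section(
    cfg: GeneratorConfig | None = None, seed: int = 0
) -> tuple[dict[str, GrayImage], SyntheticGroundTruth, np.ndarray]:
    """Render a lung section: two-lobe DAPI tissue with autofluorescence
    texture, macro lesions (soft plateaus with interior cell texture)
    and micro clusters (3-8 cells) at controlled boundary distances.

    Returns the channels, the truth table (kind = "macro"/"micro" with
    the truth boundary distance of each micro cluster to the nearest
    macro lesion), and the truth lung mask.
    """
    cfg = cfg or GeneratorConfig(height=640, width=768)
    cfg.validate()
    rng = np.random.default_rng(seed)
    lung = _lung_shape(cfg)
    sigma = cfg.blob_sigma_px
    spacing = cfg.cell_spacing_px

    lung_interior = ndi.binary_erosion(
        lung, iterations=int(cfg.lung_margin_px)
    )

    # ---- macro lesions
    n_macro = cfg.n_macro
    radii = rng.uniform(*cfg.macro_radius_px, size=n_macro)
    lung_edt = ndi.distance_transform_edt(lung)
    macro_region = lung_edt > (radii.max() + 8.0 if n_macro else 0.0)
    centers = (
        _sample_centers(
            radii + 10.0,
            cfg.height,
            cfg.width,
            rng,
            region_mask=macro_region,
            border=0.0,
        )
        if n_macro
        else np.empty((0, 2))
    )
    if cfg.adjacent_macro_gap_px is not None and n_macro >= 2:
        # move lesion 2 next to lesion 1 to create the dense-pair case
        gap = cfg.adjacent_macro_gap_px
        ang = rng.uniform(0, 2 * math.pi)
        for _ in range(100):
            d = radii[0] + radii[1] + gap
            cand = centers[0] + d * np.array([math.sin(ang), math.cos(ang)])
            ri, ci = int(cand[0]) % cfg.height, int(cand[1]) % cfg.width
            if lung_interior[ri, ci]:
                centers[1] = cand
                break
            ang += 0.3
        else:
            raise PlacementError("could not place adjacent macro pair")

    gfp_sig = np.zeros((cfg.height, cfg.width))
    rfp_sig = np.zeros_like(gfp_sig)
    signals, obj_rows, cell_rows = [], [], []
    classes = np.where(rng.random(n_macro + 0) < 0.5, "GFP+", "DsRed+")
    for i in range(n_macro):
        own = np.zeros_like(gfp_sig)
        _add_soft_disk(own, centers[i, 0], centers[i, 1], radii[i], cfg.macro_amplitude)
        # interior cell texture
        for dy, dx in _place_cells(
            max(8, int(radii[i] ** 2 / spacing**2)), radii[i], spacing, rng
        ):
            if math.hypot(dy, dx) < radii[i] - 2:
                _add_blob(own, centers[i, 0] + dy, centers[i, 1] + dx, sigma, 0.1)
        signals.append(own)
        (gfp_sig if classes[i] == "GFP+" else rfp_sig).__iadd__(own)
        obj_rows.append(
            {
                "object_id": i + 1,
                "kind": "macro",
                "fluor_class": classes[i],
                "row": centers[i, 0],
                "col": centers[i, 1],
                "cell_count": 0,
                "footprint_radius_px": radii[i],
                "gap_to_macro_px": np.nan,
            }
        )

    # truth macro mask for distance bookkeeping
    macro_mask = np.zeros_like(gfp_sig, dtype=bool)
    for sig in signals:
        macro_mask |= sig >= cfg.macro_amplitude / 2.0
    dist_to_macro = (
        ndi.distance_transform_edt(~macro_mask)
        if macro_mask.any()
        else np.full(macro_mask.shape, np.inf)
    )

    # ---- micro clusters: sample layouts first, then place
    if cfg.micro_gaps_px is not None:
        n_micro = len(cfg.micro_gaps_px)
    else:
        n_micro = cfg.n_micro
    micro_counts = [
        int(rng.integers(cfg.micro_cells[0], cfg.micro_cells[1] + 1))
        for _ in range(n_micro)
    ]
    micro_offsets = [
        _place_cells(k, _colony_radius(k, spacing), spacing, rng) for k in micro_counts
    ]
    micro_classes = np.where(rng.random(n_micro) < 0.5, "GFP+", "DsRed+")
    if cfg.micro_gaps_px is not None and n_macro:
        # the exclusion rule acts within a channel: the controlled-gap
        # clusters must share the reference lesion's reporter
        micro_classes = np.full(n_micro, classes[0])

    if cfg.micro_gaps_px is not None:
        micro_centers = _micro_centers_at_gaps(
            list(cfg.micro_gaps_px),
            micro_offsets,
            centers[0],
            radii[0],
            dist_to_macro,
            lung_interior,
            cfg,
            rng,
        )
    else:
        micro_centers = []
        lo, hi = cfg.micro_gap_px
        near = (dist_to_macro >= lo + 15) & (
            (dist_to_macro <= hi + 200) | np.isinf(dist_to_macro)
        )
        candidates = np.argwhere(lung_interior & near)
        if n_micro and candidates.size == 0:
            raise PlacementError("no room for micro clusters")
        min_sep = 3.0 * spacing
        tries = 0
        while len(micro_centers) < n_micro:
            tries += 1
            if tries > 4000:
                raise PlacementError("could not place micro clusters")
            r, c = candidates[rng.integers(len(candidates))]
            if all(math.hypot(r - pr, c - pc) > 2 * min_sep for pr, pc in micro_centers):
                micro_centers.append((float(r), float(c)))

    for j, (mr, mc) in enumerate(micro_centers):
        own = _render_cluster(
            (cfg.height, cfg.width), mr, mc, micro_offsets[j], sigma, cfg.blob_amplitude
        )
        for dy, dx in micro_offsets[j]:
            cell_rows.append(
                {
                    "cell_id": len(cell_rows) + 1,
                    "object_id": n_macro + j + 1,
                    "row": mr + dy,
                    "col": mc + dx,
                    "ki67_positive": False,
                }
            )
        signals.append(own)
        (gfp_sig if micro_classes[j] == "GFP+" else rfp_sig).__iadd__(own)
        own_mask = own >= cfg.blob_amplitude / 2.0
        true_gap = float(dist_to_macro[own_mask].min()) if own_mask.any() else np.inf
        obj_rows.append(
            {
                "object_id": n_macro + j + 1,
                "kind": "micro",
                "fluor_class": micro_classes[j],
                "row": mr,
                "col": mc,
                "cell_count": micro_counts[j],
                "footprint_radius_px": _colony_radius(micro_counts[j], spacing),
                "gap_to_macro_px": true_gap,
            }
        )

    half = min(cfg.blob_amplitude, cfg.macro_amplitude) / 2.0
    labels = _footprint_labels(signals, half, cfg)
    areas = labels.areas() if labels.n_labels else np.empty(0, dtype=int)
    for row in obj_rows:
        row["footprint_area_px"] = int(areas[row["object_id"] - 1]) if len(areas) else 0

    # ---- DAPI: tissue autofluorescence texture
    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, gfp_sig.shape), 3.0)
    texture = 0.06 * texture / max(texture.std(), 1e-9)
    dapi_sig = np.where(lung, 0.35 + texture, 0.0)

    channels = {
        "dapi": _finish(dapi_sig, cfg, rng),
        "gfp": _finish(gfp_sig, cfg, rng),
        "rfp": _finish(rfp_sig, cfg, rng),
    }
    truth = SyntheticGroundTruth(
        objects=pd.DataFrame(
            obj_rows,
            columns=[
                "object_id",
                "kind",
                "fluor_class",
                "row",
                "col",
                "cell_count",
                "footprint_radius_px",
                "gap_to_macro_px",
                "footprint_area_px",
            ],
        ),
        cells=pd.DataFrame(
            cell_rows, columns=["cell_id", "object_id", "row", "col", "ki67_positive"]
        ),
        object_labels=labels,
        params=dataclasses.asdict(cfg),
        seed=seed,
    )
    return channels, truth, lung


def _render_cluster(
    shape: tuple[int, int],
    r: float,
    c: float,
    offsets: np.ndarray,
    sigma: float,
    amp: float,
) -> np.ndarray:
    own = np.zeros(shape)
    for dy, dx in offsets:
        _add_blob(own, r + dy, c + dx, sigma, amp)
    return own


def _micro_centers_at_gaps(
    gaps: list,
    offsets_list: list[np.ndarray],
    macro_center: np.ndarray,
    macro_radius: float,
    dist_to_macro: np.ndarray,
    lung_interior: np.ndarray,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Place one micro cluster per requested boundary gap from the first
    macro lesion, on distinct rays.

    The placement iterates: render the cluster, measure the realized
    boundary distance between its truth footprint and the macro truth
    mask, and shift the cluster along its ray until the measured gap
    matches the request to within half a pixel. The stored truth
    distance is always the measured one.
    """
    shape = (cfg.height, cfg.width)
    sigma = cfg.blob_sigma_px
    out: list[tuple[float, float]] = []
    n = len(gaps)
    base = rng.uniform(0, 2 * math.pi)
    for j, gap in enumerate(gaps):
        offsets = offsets_list[j]
        placed = False
        for attempt in range(48):
            ang = base + 2 * math.pi * j / n + attempt * 0.13
            u = np.array([math.sin(ang), math.cos(ang)])
            proj = offsets @ u
            d = macro_radius + gap + cfg.nucleus_radius_px - float(proj.min())
            ok = False
            for _ in range(8):
                r, c = macro_center[0] + d * u[0], macro_center[1] + d * u[1]
                ri, ci = int(round(r)), int(round(c))
                if not (0 <= ri < cfg.height and 0 <= ci < cfg.width):
                    break
                own = _render_cluster(shape, r, c, offsets, sigma, cfg.blob_amplitude)
                mask = own >= cfg.blob_amplitude / 2.0
                if not mask.any():
                    break
                actual = float(dist_to_macro[mask].min())
                if abs(actual - gap) <= 0.5:
                    ok = lung_interior[ri, ci] and all(
                        math.hypot(r - pr, c - pc) > 40.0 for pr, pc in out
                    )
                    break
                d += gap - actual
            if ok:
                out.append((r, c))
                placed = True
                break
        if not placed:
            raise PlacementError(f"could not realize micro gap {gap} px")
    return out


# ---------------------------------------------------------------------------

def write_scene(
    channels: dict[str, GrayImage], truth: SyntheticGroundTruth, directory: str | Path
) -> list[Path]:
    """Write channel TIFFs plus truth tables for CLI / fixture use."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for tag, img in channels.items():
        path = directory / f"synthetic_{tag}.tif"
        write_channel_tiff(path, img)
        paths.append(path)
    truth.write(directory)
    return paths
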