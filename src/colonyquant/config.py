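"""Pipeline configuration.

Every tunable of the three pipelines lives here with a documented
default, so that thresholds (binarization level, h-minima depth, area
cuts, the 40-px in vivo exclusion distance, the 0.25 Ki-67 positivity
threshold) can be changed per experiment without touching code. A
config loaded from YAML and saved again round-trips losslessly.

Units
-----
Structuring-element radii are given in microns and converted through
the image pixel pitch, so the same config applies to native and
half-reduced montages. Sigmas, h values and areas are in pixels on the
processing scale; derived area cuts are expressed in "cells" and
converted through the nominal nucleus radius.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .imgops import DEFAULT_PITCH_UM, ParameterError


@dataclass
class PreprocessParams:
    """Parameters of the shared preprocessing chain
    top-hat -> Gaussian -> contrast stretch -> binarize."""

    tophat_radius_um: float
    sigma_px: float
    contrast_low_pct: float = 1.0
    contrast_high_pct: float = 99.9
    binarize_method: str = "fixed"  # "fixed" | "otsu"
    binarize_threshold: float = 0.5  # on the stretched [0, 1] scale
    #: disk decomposition for the top-hat ("sequence" is fast and very
    #: close to the exact disk; None uses the exact Euclidean disk)
    tophat_decomposition: str | None = "sequence"
    #: signal guard: the stretch span (high minus low percentile of the
    #: smoothed image) must exceed this multiple of the robust noise
    #: level (1.4826 * MAD of the top-hat image), otherwise the channel
    #: is declared empty. Prevents the contrast stretch from amplifying
    #: pure background noise above the threshold on signal-free images.
    min_signal_snr: float = 6.0

    def tophat_radius_px(self, pixel_pitch_um: float) -> int:
        return max(1, round(self.tophat_radius_um / pixel_pitch_um))


@dataclass
class PipelineConfig:
    """All tunables of the fixed, live and in vivo pipelines."""

    #: microns per pixel side after the 50% montage reduction
    pixel_pitch_um: float = DEFAULT_PITCH_UM
    #: nominal nucleus radius (um); sets the "one cell" area unit
    nucleus_radius_um: float = 7.0

    # -- in vitro preprocessing -------------------------------------------
    #: colony-scale chain (DAPI colony mask, reporter masks, live
    #: channels). The top-hat element must exceed the largest feature
    #: to keep: colonies reach ~120 um radius by day 4, so the default
    #: disk radius is 200 um.
    colony_pre: PreprocessParams = field(
        default_factory=lambda: PreprocessParams(tophat_radius_um=200.0, sigma_px=2.0)
    )
    #: nucleus-scale chain (individual nuclei, binarized Ki-67 stain)
    nucleus_pre: PreprocessParams = field(
        default_factory=lambda: PreprocessParams(tophat_radius_um=15.0, sigma_px=1.0)
    )

    # -- in vitro segmentation --------------------------------------------
    #: h-minima depth (px of distance) on the inverted colony distance map
    h_colony_px: float = 4.0
    #: h-minima depth for the nucleus-scale watershed
    h_nucleus_px: float = 0.7
    #: discard colony objects smaller than this many cell areas
    min_colony_cells: float = 4.0
    #: discard nucleus objects smaller than this (px)
    min_nucleus_area_px: int = 8

    # -- classification / Ki-67 -------------------------------------------
    #: colony-pixel overlap fraction with a reporter mask to call the class
    class_min_fraction: float = 0.5
    #: nuclear-overlap fraction above which (strictly) a nucleus is Ki-67+
    ki67_threshold: float = 0.25
    #: Ki-67 index cutoff for the "fraction of colonies above" summary
    ki67_cutoff: float = 0.8

    # -- in vivo ------------------------------------------------------------
    #: top-hat radius for the whole-section reporter channels (um)
    vivo_tophat_radius_um: float = 250.0
    #: light preprocessing chain used for the micrometastasis scan and for
    #: refining macro lesion extents
    vivo_micro_pre: PreprocessParams = field(
        default_factory=lambda: PreprocessParams(tophat_radius_um=30.0, sigma_px=1.0)
    )
    #: extended-maximum height for macro lesion seeds, on the stretched
    #: [0, 1] scale of the blurred image. The blur leaves only smooth
    #: structure, so h needs to exceed residual ripple (~0.02) while
    #: staying below the saddle between adjacent lesions (~0.2).
    h_vivo: float = 0.1
    #: threshold for the blurred macro mask (anchored stretch scale)
    vivo_binarize_threshold: float = 0.5
    #: micrometastases within this boundary distance of a macro lesion are
    #: flagged and not counted
    exclusion_px: float = 40.0
    #: micro lesion size window, in nominal cell (nucleus disk) areas.
    #: A rendered blob binarized at half-maximum after smoothing covers
    #: roughly twice the nominal nucleus disk, so 40 nominal areas
    #: corresponds to a lesion of ~20 measured cells.
    micro_min_cells: float = 2.5
    micro_max_cells: float = 40.0
    #: closing radius applied to the micro-scan mask so that the cells
    #: of one sparse seeding event join into a single candidate (px)
    micro_close_radius_px: int = 3
    #: Gaussian sigma for the lung tissue mask (px)
    lung_blur_sigma_px: float = 15.0
    #: closing radius for the lung mask (px)
    lung_close_radius_px: int = 5

    # ----------------------------------------------------------------- derived
    @property
    def nucleus_radius_px(self) -> float:
        return self.nucleus_radius_um / self.pixel_pitch_um

    @property
    def cell_area_px(self) -> float:
        """Nominal area of one nucleus in pixels (the 'cell' unit)."""
        return math.pi * self.nucleus_radius_px**2

    @property
    def min_colony_area_px(self) -> float:
        return self.min_colony_cells * self.cell_area_px

    @property
    def micro_min_area_px(self) -> float:
        return self.micro_min_cells * self.cell_area_px

    @property
    def micro_max_area_px(self) -> float:
        return self.micro_max_cells * self.cell_area_px

    @property
    def macro_min_area_px(self) -> float:
        """Macro lesions start where micro lesions end."""
        return self.micro_max_area_px

    @property
    def macro_blur_sigma_px(self) -> float:
        """Blur sigma of the in vivo Part-1 chain.

        Chosen so that a disk of the largest micro area is attenuated
        below the binarization threshold: a disk of radius r blurred by
        a Gaussian of width sigma retains a peak fraction
        1 - exp(-r^2 / (2 sigma^2)); sigma = 1.2 r / sqrt(2 ln 2) leaves
        a disk at the micro/macro size cut with ~40% of its amplitude,
        and sparse few-cell clusters (whose flux, not extent, sets their
        blurred peak) with far less.
        """
        r = math.sqrt(self.micro_max_area_px / math.pi)
        return 1.2 * r / math.sqrt(2.0 * math.log(2.0))

    def validate(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ParameterError("pixel_pitch_um must be positive")
        if not (0.0 <= self.ki67_threshold <= 1.0):
            raise ParameterError("ki67_threshold must lie in [0, 1]")
        if not (0.0 < self.class_min_fraction <= 1.0):
            raise ParameterError("class_min_fraction must lie in (0, 1]")
        if self.exclusion_px < 0:
            raise ParameterError("exclusion_px must be >= 0")
        if self.micro_min_cells >= self.micro_max_cells:
            raise ParameterError("micro_min_cells must be < micro_max_cells")

    # ----------------------------------------------------------------- io
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        for key in ("colony_pre", "nucleus_pre", "vivo_micro_pre"):
            if key in data and isinstance(data[key], dict):
                data[key] = PreprocessParams(**data[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
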