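"""Live-cell well-plate pipeline.

Without nuclear staining, colonies are segmented directly from the
native GFP/RFP reporter fluorescence using the same distance-transform
watershed chain as the fixed-cell mode, and colony area stands in for
colony size. Individual cells cannot be resolved, but colony areas and
cell counts are well correlated, so a straight-line area -> cell-count
calibration fitted on a fixed-cell assay of the same cell line yields
estimated cell counts for live colonies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .imgops import GrayImage, LabelMap, ParameterError
from .invitro_fixed import _centroids, preprocess_channel, segment_colonies


@dataclass
class LiveColonyRecord:
    colony_id: int
    channel: str  # "GFP" | "RFP"
    area_px: int
    area_um2: float
    centroid: tuple[float, float]
    estimated_cell_count: float | None = None
    timepoint: int = 0


@dataclass
class AreaCountCalibration:
    """OLS line cell_count ~ area_px fitted on fixed-cell colonies."""

    slope: float  # cells per pixel of colony area
    intercept: float  # cells
    r_squared: float
    n_points: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AreaCountCalibration":
        return cls(**json.loads(Path(path).read_text()))


def segment_live_channel(img: GrayImage, cfg: PipelineConfig | None = None) -> LabelMap:
    """Segment colonies from a native-fluorescence channel: identical
    chain to the fixed-cell colony step, applied to the reporter mask."""
    cfg = cfg or PipelineConfig()
    mask = preprocess_channel(img, cfg.colony_pre)
    return segment_colonies(mask, cfg)


def measure_live_channel(
    img: GrayImage,
    channel: str,
    cfg: PipelineConfig | None = None,
    timepoint: int = 0,
) -> list[LiveColonyRecord]:
    labels = segment_live_channel(img, cfg)
    areas = labels.areas()
    cents = _centroids(labels)
    pitch2 = labels.pixel_pitch_um**2
    return [
        LiveColonyRecord(
            colony_id=i + 1,
            channel=channel,
            area_px=int(areas[i]),
            area_um2=float(areas[i]) * pitch2,
            centroid=(float(cents[i, 0]), float(cents[i, 1])),
            timepoint=timepoint,
        )
        for i in range(labels.n_labels)
    ]


def fit_area_calibration(
    pairs: list[tuple[float, float]] | np.ndarray,
) -> AreaCountCalibration:
    """Ordinary least-squares fit of cell count against colony area.

    Requires at least 3 (area_px, cell_count) pairs with non-constant
    areas; typically the pairs come from a fixed-cell run of the same
    cell line.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ParameterError("calibration requires >= 3 (area, count) pairs")
    areas, counts = arr[:, 0], arr[:, 1]
    if np.ptp(areas) == 0:
        raise ParameterError("calibration areas are constant; fit is degenerate")
    fit = sps.linregress(areas, counts)
    return AreaCountCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_points=int(arr.shape[0]),
    )


def estimate_counts(
    records: list[LiveColonyRecord], cal: AreaCountCalibration
) -> list[LiveColonyRecord]:
    """Attach ``max(0, slope * area + intercept)`` to each record."""
    for rec in records:
        rec.estimated_cell_count = max(0.0, cal.slope * rec.area_px + cal.intercept)
    return records


def live_records_frame(records: list[LiveColonyRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
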