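"""Reading channel images, the montage-downscaling convention, and
result/manifest writing.

Channel images arrive as single-channel 8- or 16-bit TIFF or PNG, one
file per fluorescence channel (DAPI, GFP, RFP, CY5). Intensities are
normalized to [0, 1] by the dtype maximum on load. Stitched 4x montages
are reduced by 50% per linear dimension to facilitate processing, which
doubles the pixel pitch (1.346 -> 2.692 um/px).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from . import __version__
from .imgops import BinaryMask, GrayImage, LabelMap

CHANNEL_TAGS = ("dapi", "gfp", "rfp", "cy5")


class InputError(ValueError):
    """A required input file or channel is missing or unreadable."""


def read_channel(
    path: str | Path,
    channel_tag: str | None = None,
    pixel_pitch_um: float = 1.346,
    channel_index: int | None = None,
) -> GrayImage:
    """Load one grayscale channel as a [0, 1] float image.

    Parameters
    ----------
    path
        8- or 16-bit single-channel TIFF or PNG.
    channel_tag
        Optional tag ("dapi", "gfp", ...) recorded for provenance only.
    pixel_pitch_um
        Microns per pixel side of the file as acquired (native 4x
        montages: 1.346).
    channel_index
        Required selector when the file holds more than one channel.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if channel_index is None:
            raise InputError(
                f"{path} is multi-channel (shape {arr.shape}); "
                "a channel_index selector is required"
            )
        axis = int(np.argmin(arr.shape))  # channel axis is the short one
        arr = np.take(arr, channel_index, axis=axis)
    if arr.ndim != 2:
        raise InputError(f"{path} is not a 2-D image (shape {arr.shape})")
    if arr.dtype == np.uint8:
        px = arr.astype(np.float32) / 255.0
    elif arr.dtype == np.uint16:
        px = arr.astype(np.float32) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        px = np.clip(arr.astype(np.float32), 0.0, None)
    else:
        info = np.iinfo(arr.dtype)
        px = arr.astype(np.float32) / float(info.max)
    return GrayImage(px, pixel_pitch_um)


def downscale_half(img: GrayImage) -> GrayImage:
    """Reduce each linear dimension by 50% via block-mean resampling.

    Odd trailing rows/columns are dropped (13346 -> 6673), and the pixel
    pitch doubles. Block-mean (area) resampling conserves mean intensity
    exactly on even-sized images.
    """
    px = img.pixels
    h2, w2 = px.shape[0] // 2, px.shape[1] // 2
    if h2 == 0 or w2 == 0:
        raise InputError("image too small to downscale")
    px = px[: 2 * h2, : 2 * w2]
    out = px.reshape(h2, 2, w2, 2).mean(axis=(1, 3))
    return GrayImage(out, img.pixel_pitch_um * 2.0)


def discover_channels(directory: str | Path) -> dict[str, Path]:
    """Map channel tags to files named ``*_<tag>.tif/.tiff/.png`` (or
    ``<tag>.tif`` etc.) inside a directory."""
    directory = Path(directory)
    found: dict[str, Path] = {}
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in (".tif", ".tiff", ".png"):
            continue
        stem = path.stem.lower()
        for tag in CHANNEL_TAGS:
            if stem == tag or stem.endswith(f"_{tag}"):
                found.setdefault(tag, path)
    return found


# ---------------------------------------------------------------------------
# Writers

def write_channel_tiff(path: str | Path, img: GrayImage) -> None:
    """Store a [0, 1] float image as 16-bit grayscale TIFF."""
    arr = np.clip(img.pixels, 0.0, 1.0)
    tifffile.imwrite(Path(path), (arr * 65535.0 + 0.5).astype(np.uint16))


def write_label_tiff(path: str | Path, labels: LabelMap) -> None:
    """Store a label map as 16-bit TIFF (label values preserved)."""
    if labels.n_labels > 65535:
        raise InputError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(Path(path), labels.pixels.astype(np.uint16))


def write_mask_png(path: str | Path, mask: BinaryMask) -> None:
    iio.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every pipeline output set."""

    command: str
    inputs: dict[str, str]
    config: dict
    outputs: list[str] = dataclasses.field(default_factory=list)
    log: list[str] = dataclasses.field(default_factory=list)
    software_version: str = __version__
    timestamp: str = ""

    def record_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def record(self, message: str) -> None:
        self.log.append(message)

    def write(self, path: str | Path) -> None:
        self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
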