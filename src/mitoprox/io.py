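"""Reading and writing multi-channel microscopy images and ROI masks.

Images are held as per-channel 2D float arrays on their *native* intensity
scale: integer TIFF data is converted to float without any rescaling, so a
16-bit pixel of value 4095 stays 4095.0.  Thresholds downstream therefore
operate on the same numbers the microscope wrote.

Coordinate convention: row-major, origin at the top-left, 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ConfigurationError, ImageFormatError, InputError

__all__ = ["MultiChannelImage", "RoiMask", "read_image", "write_image", "read_roi", "extract_pair"]


@dataclass
class MultiChannelImage:
    """A stack of same-shaped 2D intensity channels with ordered labels.

    Parameters
    ----------
    pixels : ndarray, shape (n_channels, height, width)
        Non-negative finite intensities, float64, on the native scale of the
        source data.
    channel_names : list of str
        One label per channel, e.g. ``["mito", "protein"]``.
    bit_depth : int or "float"
        8 or 16 for integer sources, ``"float"`` for floating-point sources.
        Controls the dtype used when the image is written back to disk.
    """

    pixels: np.ndarray
    channel_names: list[str]
    bit_depth: int | str = "float"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[0] == 0:
            raise InputError("pixels must have shape (n_channels, height, width) with >= 1 channel")
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for {self.pixels.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError(f"duplicate channel names: {self.channel_names}")
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise InputError("intensities must be finite and non-negative")
        if self.bit_depth not in (8, 16, "float"):
            raise ConfigurationError(f"bit_depth must be 8, 16 or 'float', got {self.bit_depth!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[1]

    @property
    def width(self) -> int:
        return self.pixels.shape[2]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return a copy of the named channel's intensity grid."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"unknown channel {name!r}; available channels: {self.channel_names}"
            ) from None
        return self.pixels[idx].copy()


@dataclass
class RoiMask:
    """Boolean region-of-interest mask restricting analysis to one cell/area."""

    pixels: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise InputError("ROI mask must be 2D")
        if not self.pixels.any():
            raise InputError(f"ROI {self.label!r} has no pixels inside it")


def _bit_depth_of(dtype: np.dtype) -> int | str:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    return "float"


def read_image(path: str | Path, channel_names: Sequence[str] | None = None) -> MultiChannelImage:
    """Read a TIFF / OME-TIFF file into a :class:`MultiChannelImage`.

    Accepts grayscale single-plane, multi-page (one plane per channel) and
    interleaved RGB(A) TIFFs; RGB samples become separate channels in R,G,B
    order.  Integer data is converted to float without rescaling.

    Raises
    ------
    ImageFormatError
        If the file cannot be parsed as a TIFF.
    ConfigurationError
        If ``channel_names`` does not match the number of planes found.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            raw = series.asarray()
            axes = series.axes  # e.g. "YX", "QYX"/"ZYX"/"CYX", "YXS" for RGB
    except Exception as exc:  # tifffile raises several concrete types
        raise ImageFormatError(f"could not read {path} as TIFF: {exc}") from exc

    raw = np.asarray(raw)
    if raw.ndim == 2:
        planes = raw[None]
    elif raw.ndim == 3 and axes.endswith("S"):
        # interleaved RGB(A): samples last -> split in R,G,B(,A) order
        planes = np.moveaxis(raw, -1, 0)
    elif raw.ndim == 3:
        planes = raw
    else:
        raise ImageFormatError(f"unsupported TIFF layout with shape {raw.shape} in {path}")

    n = planes.shape[0]
    if channel_names is None:
        names = [f"ch{i}" for i in range(n)]
    else:
        names = list(channel_names)
        if len(names) != n:
            raise ConfigurationError(
                f"{len(names)} channel names given but {path} holds {n} plane(s)"
            )
    return MultiChannelImage(planes.astype(np.float64), names, _bit_depth_of(planes.dtype))


def write_image(path: str | Path, img: MultiChannelImage) -> None:
    """Write the image as a multi-page TIFF, one page per channel.

    Integer bit depths are written as uint8/uint16 so that a read-back is
    pixel-identical; float images are written as float32.
    """
    if img.bit_depth == 8:
        data = img.pixels.astype(np.uint8)
    elif img.bit_depth == 16:
        data = img.pixels.astype(np.uint16)
    else:
        data = img.pixels.astype(np.float32)
    tifffile.imwrite(Path(path), data, metadata={"axes": "CYX", "Labels": img.channel_names})


def read_roi(path: str | Path, label: str | None = None) -> RoiMask:
    """Load an ROI mask from a single-plane TIFF or PNG (nonzero = inside)."""
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such ROI file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            raw = tifffile.imread(path)
        else:
            raw = iio.imread(path)
    except Exception as exc:
        raise ImageFormatError(f"could not read ROI {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 3:  # RGB(A) PNG: any nonzero sample counts as inside
        raw = raw.max(axis=-1)
    if raw.ndim != 2:
        raise ImageFormatError(f"ROI {path} is not a single-plane image (shape {raw.shape})")
    return RoiMask(raw != 0, label or path.stem)


def extract_pair(img: MultiChannelImage, chan_a: str, chan_b: str) -> tuple[np.ndarray, np.ndarray]:
    """Return the two named channels, in the requested order, unchanged."""
    return img.channel(chan_a), img.channel(chan_b)
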