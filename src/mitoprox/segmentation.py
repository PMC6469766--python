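"""Channel preprocessing and threshold segmentation.

The segmentation path mirrors common confocal practice for organelle
channels: a median filter knocks down shot noise, a white top-hat (image
minus its morphological opening with a disk) removes slowly varying
background such as out-of-focus haze or illumination gradients while keeping
structures smaller than the structuring element, and a single global
threshold then separates foreground from background.  The result is a binary
mask: 1 for foreground (mitochondria / protein), 0 for background.

Because manual per-image threshold picking is not reproducible, the default
threshold method is Otsu's, with ``fixed`` and ``quantile`` overrides; the
realized threshold is always recorded on the returned mask so a run can be
reconstructed from its log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, white_tophat

from .errors import ConfigurationError, InputError
from .io import MultiChannelImage, RoiMask

__all__ = [
    "PreprocessParams",
    "ThresholdSpec",
    "BinaryMask",
    "preprocess_channel",
    "threshold_channel",
    "segment_pair",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Noise/background removal settings.

    median_radius : radius of the square median window (side 2r+1), pixels.
    tophat_radius : radius of the disk structuring element of the white
        top-hat, pixels.  Must exceed the half-width of the structures to be
        kept; 15 px is a sensible default for tubular organelles imaged at
        roughly 100 nm/pixel.
    """

    median_radius: int = 1
    tophat_radius: int = 15
    median_enabled: bool = True
    tophat_enabled: bool = True

    def __post_init__(self) -> None:
        if self.median_enabled and self.median_radius < 1:
            raise ConfigurationError("median_radius must be >= 1 when the median filter is enabled")
        if self.tophat_enabled and self.tophat_radius < 1:
            raise ConfigurationError("tophat_radius must be >= 1 when the top-hat filter is enabled")


@dataclass(frozen=True)
class ThresholdSpec:
    """How to pick the global threshold for one channel.

    method : {"otsu", "fixed", "quantile"}
        otsu      — maximize between-class variance of the histogram;
        fixed     — use ``level`` as the threshold intensity;
        quantile  — keep the upper ``level`` fraction of pixels
                    (threshold at the (1 - level) quantile).
    level : float
        Intensity for ``fixed``; upper-tail fraction in (0, 1) for
        ``quantile``; ignored for ``otsu``.
    """

    method: str = "otsu"
    level: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "fixed", "quantile"):
            raise ConfigurationError(f"unknown threshold method {self.method!r}")
        if self.method == "fixed" and (self.level is None or not np.isfinite(self.level)):
            raise ConfigurationError("fixed thresholding requires a finite level")
        if self.method == "quantile" and (self.level is None or not 0 < self.level < 1):
            raise ConfigurationError("quantile thresholding requires level in (0, 1)")


@dataclass
class BinaryMask:
    """Segmented foreground of one channel: True/1 = foreground."""

    pixels: np.ndarray
    source_channel: str = ""
    threshold: float | None = None  # realized threshold, for the run log

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise InputError("mask must be 2D")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise InputError("mask values must be exactly 0 or 1")
            arr = arr.astype(bool)
        self.pixels = arr

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


def _validate_channel(channel: np.ndarray) -> np.ndarray:
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise InputError("channel must be a 2D intensity grid")
    if not np.all(np.isfinite(channel)):
        raise InputError("channel contains non-finite intensities")
    return channel


def preprocess_channel(channel: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """Median filter, then white top-hat. Disabled filters are identities.

    Raises :class:`ConfigurationError` if an enabled filter window exceeds
    the image extent.
    """
    params = params or PreprocessParams()
    channel = _validate_channel(channel)
    if channel.min() < 0:
        raise InputError("channel intensities must be non-negative")
    h, w = channel.shape
    out = channel
    if params.median_enabled:
        side = 2 * params.median_radius + 1
        if side > min(h, w):
            raise ConfigurationError(f"median window {side} exceeds image extent {min(h, w)}")
        out = ndimage.median_filter(out, size=side, mode="reflect")
    if params.tophat_enabled:
        if 2 * params.tophat_radius + 1 > min(h, w):
            raise ConfigurationError(
                f"top-hat structuring element (radius {params.tophat_radius}) exceeds image extent"
            )
        out = white_tophat(out, footprint=disk(params.tophat_radius))
    return np.maximum(out, 0.0)


def compute_threshold(channel: np.ndarray, spec: ThresholdSpec) -> float:
    """Realized threshold for a channel under a spec.

    A constant channel under Otsu has a degenerate histogram: a warning is
    emitted and the threshold is set to the constant itself, which yields an
    all-zero mask under the strict ``intensity > threshold`` rule.
    """
    channel = _validate_channel(channel)
    if spec.method == "fixed":
        return float(spec.level)
    if spec.method == "quantile":
        return float(np.quantile(channel, 1.0 - spec.level))
    # otsu
    if channel.max() == channel.min():
        warnings.warn(
            "constant channel: Otsu threshold is degenerate, returning an all-zero mask",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(channel.flat[0])
    return float(threshold_otsu(channel))


def threshold_channel(
    channel: np.ndarray, spec: ThresholdSpec | None = None, source_channel: str = ""
) -> BinaryMask:
    """Binarize a channel: foreground where intensity is strictly above the threshold."""
    spec = spec or ThresholdSpec()
    channel = _validate_channel(channel)
    t = compute_threshold(channel, spec)
    return BinaryMask(channel > t, source_channel=source_channel, threshold=t)


def segment_pair(
    img: MultiChannelImage,
    chan_a: str,
    chan_b: str,
    params: PreprocessParams | None = None,
    spec_a: ThresholdSpec | None = None,
    spec_b: ThresholdSpec | None = None,
    roi: RoiMask | None = None,
) -> tuple[BinaryMask, BinaryMask]:
    """Preprocess and threshold two channels independently.

    If an ROI is given, pixels outside it are zeroed after preprocessing and
    before thresholding, and the final masks are restricted to the ROI.
    """
    masks = []
    for name, spec in ((chan_a, spec_a), (chan_b, spec_b)):
        channel = img.channel(name)
        if roi is not None and roi.pixels.shape != channel.shape:
            raise InputError(
                f"ROI shape {roi.pixels.shape} does not match image shape {channel.shape}"
            )
        filtered = preprocess_channel(channel, params)
        if roi is not None:
            filtered = np.where(roi.pixels, filtered, 0.0)
        mask = threshold_channel(filtered, spec, source_channel=name)
        if roi is not None:
            mask = replace(mask, pixels=mask.pixels & roi.pixels)
        masks.append(mask)
    return masks[0], masks[1]
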