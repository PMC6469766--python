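"""Colocalization statistics on binary masks.

Two statistics quantify how channel A (e.g. mitochondria) and channel B
(e.g. a protein of interest) relate spatially:

**Percent overlap** — a Jaccard-style coefficient on the two foreground
masks::

    overlap = |A AND B| / |A OR B|

1 means the masks coincide exactly, 0 means they share no pixel.  Multiplied
by 100 it is reported as a percentage.  Being purely pixel-wise, it cannot
credit structures that are adjacent but not coincident.

**Proximity index** — a sliding-window statistic in [0, 1] that also rewards
*nearby* signal.  The two masks are first averaged pixel-wise, giving 1 where
both channels are present, 0.5 where exactly one is, and 0 where neither is.
A 2^k x 2^k window (2 <= k <= 10) then sweeps the averaged image from the
top-left to the bottom-right.  In each window the *ratio factor* is the
minimum of the two foreground-count ratios, count_A/count_B and
count_B/count_A (0 if either channel is absent from the window); every pixel
in the window is multiplied by that factor, and the window's index is the
mean of its non-zero weighted pixels.  The image-level index is the sum of
the window indices divided by the number of windows with a non-zero index.
An index of 1 means the two structures overlap completely; 0 means no
similarity or the absence of one channel.

The overlap is independent of window size; the proximity index is not.  The
window-size sweep computes group means across a range of k and picks the
size that separates treatment groups most widely.  A window of 64 px (k=6)
is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .segmentation import BinaryMask

__all__ = [
    "OverlapResult",
    "ProximityConfig",
    "ProximityResult",
    "SweepResult",
    "percent_overlap",
    "average_masks",
    "window_ratio_factor",
    "window_proximity",
    "proximity_index",
    "window_size_sweep",
]

MaskLike = "BinaryMask | np.ndarray"


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.pixels
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise InputError("mask must be 2D")
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise InputError("mask values must be exactly 0 or 1")
        arr = arr.astype(bool)
    return arr


def _pair(mask_a, mask_b) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_bool(mask_a), _as_bool(mask_b)
    if a.shape != b.shape:
        raise InputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


@dataclass(frozen=True)
class OverlapResult:
    """Pixel counts and the overlap fraction of two binary masks."""

    common: int  # |A AND B|
    union: int  # |A OR B|
    overlap: float  # common / union, 0 when union == 0
    overlap_percent: float  # 100 * overlap


def percent_overlap(mask_a, mask_b) -> OverlapResult:
    """Overlap fraction = AND-count / OR-count of two same-shape binary masks.

    Both masks empty is degenerate: the fraction is defined as 0 and a
    warning is emitted.
    """
    a, b = _pair(mask_a, mask_b)
    common = int((a & b).sum())
    union = int((a | b).sum())
    if union == 0:
        warnings.warn("both masks are empty; overlap defined as 0", RuntimeWarning, stacklevel=2)
        frac = 0.0
    else:
        frac = common / union
    return OverlapResult(common=common, union=union, overlap=frac, overlap_percent=100.0 * frac)


def average_masks(mask_a, mask_b) -> np.ndarray:
    """Pixel-wise mean of two binary masks: 1 both, 0.5 one, 0 neither."""
    a, b = _pair(mask_a, mask_b)
    return (a.astype(np.float64) + b.astype(np.float64)) / 2.0


def window_ratio_factor(count_a: int, count_b: int) -> float:
    """min(count_a/count_b, count_b/count_a); 0 if either channel is absent."""
    if count_a < 0 or count_b < 0:
        raise InputError("pixel counts must be >= 0")
    if count_a == 0 or count_b == 0:
        return 0.0
    return min(count_a / count_b, count_b / count_a)


def window_proximity(averaged_window: np.ndarray, ratio: float) -> float:
    """Index of a single window: mean of the non-zero ratio-weighted pixels.

    ``averaged_window`` holds the pixel-wise mask average (values in
    {0, 0.5, 1}); every pixel is multiplied by ``ratio`` and the mean is
    taken over pixels whose weighted value is > 0 (0 if there are none).
    """
    if not 0.0 <= ratio <= 1.0:
        raise InputError("ratio factor must lie in [0, 1]")
    weighted = np.asarray(averaged_window, dtype=np.float64) * ratio
    nonzero = weighted > 0
    if not nonzero.any():
        return 0.0
    return float(weighted[nonzero].mean())


@dataclass(frozen=True)
class ProximityConfig:
    """Window geometry of the proximity-index sweep.

    k : window exponent; the window is 2^k x 2^k pixels, 2 <= k <= 10.
    stride : step between window origins; default (None) equals the window
        size, i.e. a non-overlapping tiling, so each pixel is counted once
        and the denominator "number of windows" is unambiguous.
    edge_policy : what to do when the image side is not a multiple of the
        window size — "partial" keeps truncated right/bottom windows so the
        whole image is scanned (default), "pad" zero-pads to a full tiling
        (identical indices to "partial", since padded zeros are never part
        of the non-zero-pixel average), "drop" discards partial windows.
    """

    k: int = 6
    stride: int | None = None
    edge_policy: str = "partial"

    def __post_init__(self) -> None:
        if not (isinstance(self.k, (int, np.integer)) and 2 <= self.k <= 10):
            raise ConfigurationError(f"k must be an integer in [2, 10], got {self.k!r}")
        if self.stride is not None and self.stride < 1:
            raise ConfigurationError("stride must be >= 1")
        if self.edge_policy not in ("partial", "pad", "drop"):
            raise ConfigurationError(f"unknown edge policy {self.edge_policy!r}")

    @property
    def window_size(self) -> int:
        return 2**self.k


@dataclass
class ProximityResult:
    """Per-window indices and the aggregated image-level proximity index."""

    per_window_index: np.ndarray  # (n_window_rows, n_window_cols)
    n_nonzero_windows: int
    proximity_index: float
    config: ProximityConfig


def _window_starts(extent: int, window: int, stride: int, edge_policy: str) -> np.ndarray:
    starts = np.arange(0, extent, stride)
    if edge_policy == "drop":
        starts = starts[starts + window <= extent]
    return starts


def proximity_index(mask_a, mask_b, config: ProximityConfig | None = None) -> ProximityResult:
    """Sliding-window proximity index of two binary masks.

    The averaged image is swept from top-left to bottom-right by a
    ``2^k x 2^k`` window; each window contributes the mean of its non-zero
    ratio-weighted pixels, and the image index is the sum of window indices
    divided by the number of windows with a non-zero index (0 if none).
    """
    config = config or ProximityConfig()
    a, b = _pair(mask_a, mask_b)
    h, w = a.shape
    win = config.window_size
    if win > min(h, w):
        raise ConfigurationError(f"window size {win} exceeds image extent {min(h, w)}")
    stride = config.stride if config.stride is not None else win

    # Integral images give O(1) per-window foreground counts for A, B and
    # their union; the windowed sum of the averaged image is (sum_A+sum_B)/2
    # and the count of non-zero averaged pixels is the union count, so each
    # window index reduces to ratio * avg_sum / union_count.
    def _integral(m: np.ndarray) -> np.ndarray:
        s = np.zeros((h + 1, w + 1), dtype=np.int64)
        np.cumsum(np.cumsum(m, axis=0), axis=1, out=s[1:, 1:])
        return s

    sa, sb, su = _integral(a), _integral(b), _integral(a | b)
    rows = _window_starts(h, win, stride, config.edge_policy)
    cols = _window_starts(w, win, stride, config.edge_policy)
    r0, c0 = np.meshgrid(rows, cols, indexing="ij")
    r1, c1 = np.minimum(r0 + win, h), np.minimum(c0 + win, w)

    def _window_sum(s: np.ndarray) -> np.ndarray:
        return s[r1, c1] - s[r0, c1] - s[r1, c0] + s[r0, c0]

    na, nb, nu = _window_sum(sa), _window_sum(sb), _window_sum(su)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((na > 0) & (nb > 0), np.minimum(na / np.maximum(nb, 1), nb / np.maximum(na, 1)), 0.0)
        avg_sum = (na + nb) / 2.0
        per_window = np.where(nu > 0, ratio * avg_sum / np.maximum(nu, 1), 0.0)

    nonzero = int((per_window > 0).sum())
    index = float(per_window.sum() / nonzero) if nonzero > 0 else 0.0
    return ProximityResult(
        per_window_index=per_window,
        n_nonzero_windows=nonzero,
        proximity_index=index,
        config=config,
    )


@dataclass
class SweepResult:
    """Group means of the proximity index across window exponents k."""

    per_k_group_means: pd.DataFrame  # index k, one column per group
    separation: pd.Series  # index k -> max pairwise |group-mean difference|
    selected_k: int


def window_size_sweep(
    grouped_pairs: Mapping[str, Sequence[tuple]],
    k_range: Iterable[int] = range(2, 11),
    stride: int | None = None,
    edge_policy: str = "partial",
) -> SweepResult:
    """Pick the window size that separates treatment groups most widely.

    For every k in ``k_range`` the mean proximity index is computed per
    group; the separation at k is the largest absolute difference between
    any two group means, and the selected k maximizes it (ties broken toward
    the smaller k, i.e. the finer granularity).
    """
    groups = {str(label): list(pairs) for label, pairs in grouped_pairs.items()}
    if len(groups) < 2:
        raise ConfigurationError("window-size sweep needs at least 2 groups")
    for label, pairs in groups.items():
        if not pairs:
            raise ConfigurationError(f"group {label!r} has no mask pairs")
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ConfigurationError("empty k range")

    means: dict[int, dict[str, float]] = {}
    for k in ks:
        cfg = ProximityConfig(k=k, stride=stride, edge_policy=edge_policy)
        means[k] = {
            label: float(np.mean([proximity_index(a, b, cfg).proximity_index for a, b in pairs]))
            for label, pairs in groups.items()
        }
    table = pd.DataFrame.from_dict(means, orient="index").sort_index()
    table.index.name = "k"

    vals = table.to_numpy()
    separation = pd.Series(vals.max(axis=1) - vals.min(axis=1), index=table.index, name="separation")
    selected_k = int(separation.idxmax())  # idxmax returns the first (smallest) k on ties
    return SweepResult(per_k_group_means=table, separation=separation, selected_k=selected_k)
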