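"""Independent reference implementations used only to check the package.

These are deliberately naive — explicit Python loops straight from the
stepwise definitions — and share no code with the vectorized production
paths they verify.
"""

from __future__ import annotations

import numpy as np


def brute_overlap(a: np.ndarray, b: np.ndarray) -> tuple[int, int, float]:
    """AND/OR pixel counting by explicit iteration."""
    common = union = 0
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            if a[r, c] and b[r, c]:
                common += 1
            if a[r, c] or b[r, c]:
                union += 1
    return common, union, (common / union if union else 0.0)


def naive_proximity_index(
    a: np.ndarray, b: np.ndarray, window: int, stride: int | None = None, edge: str = "partial"
) -> float:
    """Window-by-window loop over the averaged image, per the stepwise recipe:
    average the masks, tile with the window, per window take
    min(countA/countB, countB/countA) (0 if either absent), weight every
    pixel by it, average the non-zero weighted pixels; finally divide the
    summed window indices by the number of non-zero windows.
    """
    a = a.astype(bool)
    b = b.astype(bool)
    avg = (a.astype(float) + b.astype(float)) / 2.0
    h, w = a.shape
    stride = stride or window
    indices = []
    for r0 in range(0, h, stride):
        for c0 in range(0, w, stride):
            if edge == "drop" and (r0 + window > h or c0 + window > w):
                continue
            r1, c1 = min(r0 + window, h), min(c0 + window, w)
            na = int(a[r0:r1, c0:c1].sum())
            nb = int(b[r0:r1, c0:c1].sum())
            ratio = min(na / nb, nb / na) if na > 0 and nb > 0 else 0.0
            weighted = avg[r0:r1, c0:c1] * ratio
            nz = weighted > 0
            indices.append(float(weighted[nz].mean()) if nz.any() else 0.0)
    nonzero = [v for v in indices if v > 0]
    return sum(indices) / len(nonzero) if nonzero else 0.0


def brute_otsu(values: np.ndarray) -> float:
    """Otsu threshold by exhaustive search over the distinct intensities:
    the threshold maximizing between-class variance, with foreground taken
    strictly above it."""
    flat = np.sort(values.ravel())
    candidates = np.unique(flat)[:-1]  # splitting above the max leaves one class
    best_t, best_var = candidates[0], -1.0
    n = flat.size
    for t in candidates:
        lo = flat[flat <= t]
        hi = flat[flat > t]
        w0, w1 = lo.size / n, hi.size / n
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return float(best_t)
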