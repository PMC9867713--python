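"""Automatic histogram thresholds: exact Otsu and Huang (minimum fuzzy entropy).

Both operate on the exact integer histogram of the image, not a rebinned
one, so the returned level is the true optimizer over every gray level the
image can take. The search is restricted to the occupied range
[min(image), max(image)] — a threshold outside that range separates nothing,
so the optimum over the occupied range equals the optimum over the full
16-bit range. Pixels with value <= threshold are background, > threshold
foreground.
"""

from __future__ import annotations

import numpy as np

from .types import DataError

__all__ = ["threshold_otsu_exact", "threshold_huang"]


def _integer_histogram(image: np.ndarray) -> tuple[np.ndarray, int]:
    """Histogram of counts over levels lo..hi; returns (counts, lo)."""
    flat = np.asarray(image).ravel()
    if flat.size == 0:
        raise DataError("cannot threshold an empty image")
    if not np.issubdtype(flat.dtype, np.integer):
        if not np.allclose(flat, np.round(flat)):
            raise DataError("thresholds operate on integer-valued images")
        flat = np.round(flat).astype(np.int64)
    lo = int(flat.min())
    hi = int(flat.max())
    counts = np.bincount((flat - lo).astype(np.int64), minlength=hi - lo + 1)
    return counts.astype(np.float64), lo


def threshold_otsu_exact(image: np.ndarray) -> int:
    """Gray level maximizing the between-class variance.

    Equivalent to exhaustive search over every integer level; ties resolved
    to the lowest optimal level. Raises if the image is constant.
    """
    counts, lo = _integer_histogram(image)
    if np.count_nonzero(counts) < 2:
        raise DataError("image is constant; Otsu threshold undefined")
    levels = np.arange(counts.size, dtype=np.float64)
    w0 = np.cumsum(counts)
    total = w0[-1]
    w1 = total - w0
    csum = np.cumsum(counts * levels)
    gsum = csum[-1]
    # candidate thresholds t = lo..hi-1, classes (<= t) vs (> t)
    valid = (w0[:-1] > 0) & (w1[:-1] > 0)
    mu0 = np.where(valid, csum[:-1] / np.where(w0[:-1] > 0, w0[:-1], 1), 0.0)
    mu1 = np.where(valid, (gsum - csum[:-1]) / np.where(w1[:-1] > 0, w1[:-1], 1), 0.0)
    var_between = np.where(valid, w0[:-1] * w1[:-1] * (mu0 - mu1) ** 2, -np.inf)
    return lo + int(np.argmax(var_between))


def threshold_huang(image: np.ndarray, chunk: int = 512) -> int:
    """Gray level minimizing Huang's measure of fuzziness.

    For a threshold t, pixels are given fuzzy memberships
    ``u(g) = 1 / (1 + |g - mu_class| / C)`` (C = dynamic range; mu_class the
    mean of the pixel's side of t) and the Shannon entropy
    ``S(u) = -u ln u - (1-u) ln(1-u)`` is accumulated over the histogram; the
    threshold with minimal total entropy is returned (ties -> lowest level).
    The scan over candidate levels is chunked to bound memory.
    """
    counts, lo = _integer_histogram(image)
    if np.count_nonzero(counts) < 2:
        raise DataError("image is constant; Huang threshold undefined")
    n_levels = counts.size
    levels = np.arange(n_levels, dtype=np.float64)
    c_range = float(levels[-1] - levels[0])
    w0 = np.cumsum(counts)
    csum = np.cumsum(counts * levels)
    total_w, total_s = w0[-1], csum[-1]

    cand = np.arange(n_levels - 1)
    valid = (w0[cand] > 0) & ((total_w - w0[cand]) > 0)
    best_t, best_e = None, np.inf
    for start in range(0, cand.size, chunk):
        t = cand[start : start + chunk][valid[start : start + chunk]]
        if t.size == 0:
            continue
        mu0 = csum[t] / w0[t]  # (T,)
        mu1 = (total_s - csum[t]) / (total_w - w0[t])
        # membership of every level under every candidate threshold: (T, L)
        dist0 = np.abs(levels[None, :] - mu0[:, None])
        dist1 = np.abs(levels[None, :] - mu1[:, None])
        below = levels[None, :] <= t[:, None]
        u = 1.0 / (1.0 + np.where(below, dist0, dist1) / c_range)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = -u * np.log(u) - (1.0 - u) * np.log1p(-u)
        s = np.nan_to_num(s, nan=0.0)  # u == 1 contributes zero entropy
        entropy = s @ counts
        k = int(np.argmin(entropy))
        if entropy[k] < best_e:
            best_e, best_t = float(entropy[k]), int(t[k])
    assert best_t is not None
    return lo + best_t
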