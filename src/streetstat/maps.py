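"""Dense local contrast and spatial-frequency (kurtosis) maps.

Around every pixel of a grayscale image a square neighborhood is
vectorized column-major and pushed through two workflows:

* contrast map C — each entry is the RMS contrast of the neighborhood,
  i.e. the population standard deviation of its luminance values;
* kurtosis map K — the neighborhood is log-transformed, projected onto
  a learned IC filter bank, and each entry is the Pearson kurtosis of
  the resulting response vector.  Sparse responses (low-frequency
  content) give high kurtosis; dense responses (high-frequency
  content) give low kurtosis, so K segments local spatial frequency.

Both maps cover only the valid region (no padding): at stride 1 an
H x W image with neighborhood side s yields (H-s+1) x (W-s+1) maps.
Dense computation is vectorized internally but contractually equal to
per-neighborhood brute force.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .ica import FilterBank

#: Response variance below this is treated as degenerate (kurtosis undefined).
VARIANCE_FLOOR = 1e-12


def vectorize_neighborhood(patch: np.ndarray) -> np.ndarray:
    """Vectorize a square neighborhood column-wise.

    Pixels are read top-to-bottom then left-to-right, so
    ``[[1, 2], [3, 4]]`` becomes ``(1, 3, 2, 4)``.
    """
    patch = np.asarray(patch)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"neighborhood must be square 2-D, got shape {patch.shape}")
    return patch.flatten(order="F")


def rms_contrast(x: np.ndarray) -> float:
    """RMS contrast of a neighborhood vector.

    The population standard deviation (divisor n) of the luminance
    values, in luminance levels.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for RMS contrast")
    return float(np.std(x))


def log_transform(x: np.ndarray) -> np.ndarray:
    """Elementwise luminance normalization: ln(v) for v > 0, 0 at v = 0.

    Compresses large luminance differences before filtering; output is
    always finite.  Negative luminance is rejected.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("luminance values must be nonnegative")
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = np.log(x[pos])
    return out


def filter_responses(xt: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Responses of every filter in the bank to a transformed neighborhood.

    Non-DC responses are inner products ``w_k . xt``; the entry at the
    bank's DC index is pinned to the bank's constant ``c``.
    """
    xt = np.asarray(xt, dtype=float)
    if xt.shape != (bank.patch_dim,):
        raise ValueError(
            f"neighborhood vector length {xt.shape} does not match bank "
            f"patch dimensionality {bank.patch_dim}")
    a = bank.filters @ xt
    a[bank.dc_index] = bank.dc_constant
    return a


def response_kurtosis(a: np.ndarray) -> float:
    """Pearson (non-excess) kurtosis of a response vector.

    Population moments: fourth central moment over squared variance.
    Returns NaN when the response variance is below the degeneracy
    floor (the map machinery masks such entries).
    """
    a = np.asarray(a, dtype=float)
    if a.size < 4:
        raise ValueError("need at least 4 responses for kurtosis")
    d = a - a.mean()
    m2 = np.mean(d ** 2)
    if m2 < VARIANCE_FLOOR:
        return float("nan")
    return float(np.mean(d ** 4) / m2 ** 2)


def _check_window(img: np.ndarray, size: int, stride: int) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if size < 2:
        raise ValueError("neighborhood size must be >= 2")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if img.shape[0] < size or img.shape[1] < size:
        raise ValueError(
            f"image {img.shape} smaller than {size}x{size} neighborhood")
    return img


def map_shape(image_shape, size: int, stride: int = 1):
    """Output map dimensions for the valid-region sliding window."""
    h, w = image_shape
    return ((h - size) // stride + 1, (w - size) // stride + 1)


def contrast_map(img: np.ndarray, size: int = 16, stride: int = 1) -> np.ndarray:
    """RMS-contrast map over the valid region.

    ``C[i, j]`` is the population standard deviation of the
    ``size x size`` neighborhood whose top-left corner is at
    ``(i*stride, j*stride)``.
    """
    img = _check_window(img, size, stride)
    nh, nw = map_shape(img.shape, size, stride)
    # accumulate shifted slices; subtracting the global mean first keeps
    # the E[x^2] - E[x]^2 form well conditioned at 1e-9 accuracy
    x = img - img.mean()
    s1 = np.zeros((nh, nw))
    s2 = np.zeros((nh, nw))
    for di in range(size):
        for dj in range(size):
            sl = x[di:di + (nh - 1) * stride + 1:stride,
                   dj:dj + (nw - 1) * stride + 1:stride]
            s1 += sl
            s2 += sl ** 2
    n = size * size
    var = s2 / n - (s1 / n) ** 2
    np.maximum(var, 0.0, out=var)
    return np.sqrt(var)


def kurtosis_map(img: np.ndarray, bank: FilterBank, size: int | None = None,
                 stride: int = 1, row_block: int = 64) -> np.ma.MaskedArray:
    """Response-kurtosis map over the valid region.

    Each entry is ``response_kurtosis(filter_responses(log_transform(
    vectorize(neighborhood))))`` for the neighborhood at that position.
    Entries whose response variance is degenerate are masked.  The
    neighborhood side must match the bank's patch support.
    """
    if size is None:
        size = bank.patch_size
    if size != bank.patch_size:
        raise ValueError(
            f"neighborhood size {size} does not match bank patch size "
            f"{bank.patch_size}")
    img = _check_window(img, size, stride)
    nh, nw = map_shape(img.shape, size, stride)
    windows = sliding_window_view(img, (size, size))[::stride, ::stride]
    values = np.empty((nh, nw))
    mask = np.zeros((nh, nw), dtype=bool)
    m = bank.n_filters
    wt = bank.filters.T  # (d, m)
    for i0 in range(0, nh, row_block):
        i1 = min(i0 + row_block, nh)
        # column-major patch vectorization: transpose each window
        block = windows[i0:i1].transpose(0, 1, 3, 2).reshape(-1, size * size)
        blk = log_transform(block)
        a = blk @ wt
        a[:, bank.dc_index] = bank.dc_constant
        d = a - a.mean(axis=1, keepdims=True)
        m2 = np.mean(d ** 2, axis=1)
        m4 = np.mean(d ** 4, axis=1)
        bad = m2 < VARIANCE_FLOOR
        k = np.full(m2.shape, np.nan)
        np.divide(m4, m2 ** 2, out=k, where=~bad)
        values[i0:i1] = k.reshape(i1 - i0, nw)
        mask[i0:i1] = bad.reshape(i1 - i0, nw)
    _ = m
    return np.ma.MaskedArray(values, mask=mask)
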