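"""The combined complexity measure M from map statistics.

Four statistics summarize the two maps: the mean and standard
deviation of the contrast map (mu_C, sigma_C) and the skewness and
kurtosis of the kurtosis-map values (S_K, K_K).  Each of the first
three rises with perceived complexity — more high-contrast structures
raise mu_C and sigma_C, and an excess of regions at lower spatial
frequencies than the scene average skews the kurtosis-map distribution
to the right, raising S_K.  K_K instead flags heavy right-tail
outliers in the kurtosis map, so it enters the denominator to
compensate S_K values inflated by a few extreme entries:

    M = mu_C * sigma_C * S_K / K_K

All moments are population (divisor-n) moments, and kurtosis is
non-excess (Pearson), so K_K >= 1 and the denominator never vanishes.
Masked (undefined-kurtosis) map entries are excluded from the
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import maps as _maps
from .ica import FilterBank

log = logging.getLogger(__name__)


@dataclass
class ComplexityStatistics:
    """Map statistics and their combination for one image."""

    mu_c: float      # mean of contrast map, luminance levels
    sigma_c: float   # std of contrast map, luminance levels
    skew_k: float    # skewness of kurtosis-map values, unitless
    kurt_k: float    # Pearson kurtosis of kurtosis-map values, >= 1
    m: float         # combined measure


def contrast_statistics(cmap: np.ndarray) -> tuple[float, float]:
    """Population mean and standard deviation of a contrast map."""
    cmap = np.asarray(cmap, dtype=float)
    if cmap.size == 0:
        raise ValueError("empty contrast map")
    return float(cmap.mean()), float(cmap.std())


def kurtosis_statistics(kmap: np.ndarray) -> tuple[float, float]:
    """Population skewness and Pearson kurtosis of the defined map entries.

    Masked entries (degenerate neighborhoods) are excluded; the
    excluded fraction is logged.  A map with fewer than 4 defined
    entries or zero variance has no defined statistics.
    """
    if np.ma.isMaskedArray(kmap):
        values = kmap.compressed()
        excluded = kmap.mask.sum() if kmap.mask is not np.ma.nomask else 0
        if excluded:
            log.info("kurtosis map: %d/%d entries undefined, excluded",
                     excluded, kmap.size)
    else:
        values = np.asarray(kmap, dtype=float).ravel()
    if values.size < 4:
        raise ValueError("need at least 4 defined kurtosis-map entries")
    d = values - values.mean()
    m2 = np.mean(d ** 2)
    if m2 < 1e-12:
        raise ValueError("kurtosis map is degenerate (zero variance)")
    skew = float(np.mean(d ** 3) / m2 ** 1.5)
    kurt = float(np.mean(d ** 4) / m2 ** 2)
    return skew, kurt


def complexity_measure(mu_c: float, sigma_c: float, skew_k: float,
                       kurt_k: float) -> float:
    """Combine the four map statistics into the complexity measure M.

    M = mu_C * sigma_C * S_K / K_K.  The three numerator statistics
    each correlate positively with perceived complexity; the
    kurtosis-map kurtosis divides through to discount skewness driven
    by outliers.  M carries the sign of S_K.
    """
    if not all(np.isfinite(v) for v in (mu_c, sigma_c, skew_k, kurt_k)):
        raise ValueError("complexity statistics must be finite")
    if kurt_k < 1:
        raise ValueError(f"K_K = {kurt_k} below the Pearson lower bound 1")
    return mu_c * sigma_c * skew_k / kurt_k


def measure_image(img: np.ndarray, bank: FilterBank, size: int = 16,
                  stride: int = 1) -> ComplexityStatistics:
    """End-to-end complexity statistics for one grayscale image.

    Computes both maps at the given neighborhood size and stride and
    returns all four statistics alongside M, so per-statistic analyses
    against subjective ranks remain possible.
    """
    cmap = _maps.contrast_map(img, size=size, stride=stride)
    kmap = _maps.kurtosis_map(img, bank, size=size, stride=stride)
    mu_c, sigma_c = contrast_statistics(cmap)
    skew_k, kurt_k = kurtosis_statistics(kmap)
    m = complexity_measure(mu_c, sigma_c, skew_k, kurt_k)
    return ComplexityStatistics(mu_c=mu_c, sigma_c=sigma_c, skew_k=skew_k,
                                kurt_k=kurt_k, m=m)
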