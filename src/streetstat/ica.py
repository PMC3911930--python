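"""Independent-component filter banks learned from image patches.

A bank of wavelet-like filters is learned by FastICA from patches of
photographic or textured images.  Because ICA whitens its input, the
learned filters concentrate at the high-frequency end of the Fourier
spectrum, which is what makes their pooled response activity a usable
local spatial-frequency probe: high-frequency content drives many
filters (dense responses, low kurtosis), low-frequency content drives
few (sparse responses, high kurtosis).

One learned component represents mean patch luminance (the DC
component); it is flagged so the response machinery can pin its
response to a constant.  Each non-DC filter is characterized by a
least-squares 2-D Gabor fit, yielding its preferred spatial frequency
(cycles/pixel), orientation (degrees) and half-amplitude spatial
frequency bandwidth (octaves).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.decomposition import FastICA

_LN2 = np.log(2.0)


@dataclass
class FilterBank:
    """Learned IC filters on a square patch support.

    Attributes
    ----------
    filters : (m, d) array
        One unit-norm filter per row, d = patch_size**2, in the same
        column-major patch vectorization used throughout the package.
    dc_index : int
        Row index of the DC (mean-luminance) component.
    patch_size : int
        Side length of the square patch support.
    dc_constant : float
        Constant response assigned to the DC filter.
    seed : int or None
        RNG seed used for learning, recorded for provenance.
    """

    filters: np.ndarray
    dc_index: int
    patch_size: int
    dc_constant: float = 0.0
    seed: int | None = None

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    @property
    def patch_dim(self) -> int:
        return self.patch_size ** 2

    def non_dc_indices(self) -> np.ndarray:
        return np.array([k for k in range(self.n_filters) if k != self.dc_index])

    def save(self, path) -> None:
        np.savez(
            path,
            filters=self.filters,
            dc_index=self.dc_index,
            patch_size=self.patch_size,
            dc_constant=self.dc_constant,
            seed=-1 if self.seed is None else self.seed,
        )

    @classmethod
    def load(cls, path) -> "FilterBank":
        with np.load(path) as z:
            seed = int(z["seed"])
            return cls(
                filters=z["filters"],
                dc_index=int(z["dc_index"]),
                patch_size=int(z["patch_size"]),
                dc_constant=float(z["dc_constant"]),
                seed=None if seed < 0 else seed,
            )


@dataclass
class GaborParams:
    """Fitted Gabor characterization of one filter."""

    center_frequency: float  # cycles/pixel
    orientation: float       # degrees, in [0, 180)
    bandwidth: float         # octaves (inf when the envelope reaches DC)
    fit_residual: float      # relative residual norm, inf on divergence

    @property
    def reliable(self) -> bool:
        return np.isfinite(self.fit_residual)


def sample_patches(images, n_patches: int, patch_size: int = 16,
                   seed: int = 0) -> np.ndarray:
    """Extract non-overlapping square patches from a set of images.

    Each image contributes the cells of its non-overlapping
    ``patch_size`` grid; ``n_patches`` cells are drawn uniformly (without
    replacement) from the pooled grid, deterministically for a given
    seed.  Returns an (n_patches, patch_size**2) matrix with patches
    vectorized column-major (top-to-bottom, then left-to-right).
    """
    if n_patches < 0:
        raise ValueError("n_patches must be nonnegative")
    cells = []
    for idx, img in enumerate(images):
        img = np.asarray(img, dtype=float)
        if img.ndim != 2:
            raise ValueError(f"image {idx} is not 2-D grayscale")
        if min(img.shape) < patch_size:
            raise ValueError(
                f"image {idx} with shape {img.shape} is smaller than the "
                f"{patch_size}x{patch_size} patch support")
        for i in range(img.shape[0] // patch_size):
            for j in range(img.shape[1] // patch_size):
                cells.append((idx, i * patch_size, j * patch_size))
    if n_patches > len(cells):
        raise ValueError(
            f"requested {n_patches} patches but only {len(cells)} "
            f"non-overlapping grid cells are available")
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(len(cells))[:n_patches]
    d = patch_size ** 2
    out = np.empty((n_patches, d), dtype=float)
    imgs = [np.asarray(img, dtype=float) for img in images]
    for row, c in enumerate(chosen):
        idx, i, j = cells[c]
        patch = imgs[idx][i:i + patch_size, j:j + patch_size]
        out[row] = patch.flatten(order="F")
    return out


def _dc_index(filters: np.ndarray, patch_size: int) -> int:
    """Index of the filter whose spectrum is most concentrated at DC."""
    best, best_ratio = 0, -1.0
    for k, w in enumerate(filters):
        spec = np.abs(np.fft.fft2(w.reshape(patch_size, patch_size, order="F")))
        ratio = spec[0, 0] / spec.sum()
        if ratio > best_ratio:
            best, best_ratio = k, ratio
    return best


def _orient_filter(w: np.ndarray, patch_size: int) -> np.ndarray:
    """Fix the sign ambiguity left by ICA.

    The filter is flipped, if needed, so that the carrier phase at the
    patch center is nonnegative: the DFT coefficient at the spectral
    peak, phase-referenced to the patch center, must have nonnegative
    real part.  Downstream kurtosis is invariant to this choice.
    """
    s = patch_size
    patch = w.reshape(s, s, order="F")
    spec = np.fft.fft2(patch)
    mag = np.abs(spec)
    ku, kv = np.unravel_index(np.argmax(mag), mag.shape)
    cy = cx = (s - 1) / 2.0
    phase_shift = np.exp(2j * np.pi * (np.fft.fftfreq(s)[ku] * cy
                                       + np.fft.fftfreq(s)[kv] * cx))
    if (spec[ku, kv] * phase_shift).real < 0:
        return -w
    return w


def learn_filters(patches: np.ndarray, iterations: int = 200,
                  nonlinearity: str = "tanh", seed: int = 0,
                  tol: float = 1e-4) -> FilterBank:
    """Learn an IC filter bank from a patch matrix with FastICA.

    No dimension reduction is applied: the number of learned filters
    equals the patch dimensionality d (so 16 x 16 patches yield 256
    components, of which one is flagged DC).  The working nonlinearity
    is the hyperbolic tangent.  Filters are normalized to unit
    Euclidean norm with a deterministic sign convention.
    """
    patches = np.asarray(patches, dtype=float)
    n, d = patches.shape
    if n < d:
        raise ValueError(
            f"need at least d={d} patches to learn d components, got {n}")
    patch_size = int(round(np.sqrt(d)))
    if patch_size ** 2 != d:
        raise ValueError(f"patch dimensionality {d} is not a perfect square")
    cov_eig = np.linalg.eigvalsh(np.cov(patches, rowvar=False))
    if cov_eig[0] <= 1e-10 * cov_eig[-1]:
        raise ValueError(
            "patch covariance is (near-)rank-deficient; supply more or "
            "more varied patches")
    fun = {"tanh": "logcosh", "logcosh": "logcosh",
           "cube": "cube", "exp": "exp"}.get(nonlinearity)
    if fun is None:
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    ica = FastICA(n_components=d, algorithm="parallel", fun=fun,
                  whiten="unit-variance", max_iter=iterations, tol=tol,
                  random_state=np.random.RandomState(seed))
    import warnings
    with warnings.catch_warnings():
        # the iteration cap is part of the learning recipe, not a failure
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        ica.fit(patches)
    filters = ica.components_.copy()
    filters /= np.linalg.norm(filters, axis=1, keepdims=True)
    for k in range(d):
        filters[k] = _orient_filter(filters[k], patch_size)
    dc = _dc_index(filters, patch_size)
    return FilterBank(filters=filters, dc_index=dc, patch_size=patch_size,
                      seed=seed)


# ---------------------------------------------------------------------------
# Gabor characterization


def gabor_patch(patch_size: int, amplitude: float, x0: float, y0: float,
                sigma_x: float, sigma_y: float, frequency: float,
                theta_rad: float, phase: float) -> np.ndarray:
    """Evaluate a 2-D Gabor on a ``patch_size`` grid.

    The carrier runs along the rotated x' axis: rows are image y
    (downward), columns are image x, ``theta_rad`` is measured
    counterclockwise from the horizontal image axis.
    """
    yy, xx = np.mgrid[0:patch_size, 0:patch_size].astype(float)
    xr = (xx - x0) * np.cos(theta_rad) + (yy - y0) * np.sin(theta_rad)
    yr = -(xx - x0) * np.sin(theta_rad) + (yy - y0) * np.cos(theta_rad)
    env = np.exp(-(xr ** 2 / (2 * sigma_x ** 2) + yr ** 2 / (2 * sigma_y ** 2)))
    return amplitude * env * np.cos(2 * np.pi * frequency * xr + phase)


def gabor_half_amplitude_bandwidth(frequency: float, sigma_x: float) -> float:
    """Half-amplitude spatial-frequency bandwidth of a Gabor, in octaves.

    The amplitude spectrum of a Gaussian-envelope Gabor is Gaussian
    around the carrier frequency with half-amplitude half-width
    ``sqrt(ln 2 / 2) / (pi * sigma_x)``; the bandwidth is
    ``log2(f_hi / f_lo)`` and diverges when the envelope reaches DC.
    """
    half_width = np.sqrt(_LN2 / 2.0) / (np.pi * sigma_x)
    f_lo = frequency - half_width
    f_hi = frequency + half_width
    if f_lo <= 0:
        return np.inf
    return float(np.log2(f_hi / f_lo))


def _initial_gabor_guess(patch: np.ndarray):
    s = patch.shape[0]
    spec = np.fft.fft2(patch)
    mag = np.abs(spec)
    fy = np.fft.fftfreq(s)
    fx = np.fft.fftfreq(s)
    mag_search = mag.copy()
    mag_search[0, 0] = 0.0  # carrier, not DC
    ku, kv = np.unravel_index(np.argmax(mag_search), mag_search.shape)
    f_v, f_h = fy[ku], fx[kv]
    f0 = float(np.hypot(f_h, f_v))
    theta0 = float(np.arctan2(f_v, f_h)) % np.pi
    w = np.abs(patch)
    w_sum = w.sum()
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    x0 = float((xx * w).sum() / w_sum)
    y0 = float((yy * w).sum() / w_sum)
    var_x = float(((xx - x0) ** 2 * w).sum() / w_sum)
    var_y = float(((yy - y0) ** 2 * w).sum() / w_sum)
    sigma0 = max(np.sqrt((var_x + var_y) / 2), 0.5)
    amp0 = float(np.abs(patch).max())
    return amp0, x0, y0, sigma0, sigma0, f0, theta0, 0.0


def fit_gabor(filt: np.ndarray, patch_size: int) -> GaborParams:
    """Characterize one non-DC filter by a least-squares 2-D Gabor fit.

    Returns the fitted carrier frequency (cycles/pixel) and orientation
    (degrees in [0, 180)), and the half-amplitude bandwidth in octaves
    implied by the fitted envelope.  A divergent fit is flagged with
    ``fit_residual = inf`` rather than raising.
    """
    filt = np.asarray(filt, dtype=float)
    patch = filt.reshape(patch_size, patch_size, order="F")
    norm = np.linalg.norm(patch)
    if norm == 0 or np.std(patch) < 1e-12 * max(1.0, np.abs(patch).max()):
        raise ValueError("constant (DC-like) input has no Gabor characterization")
    spec = np.abs(np.fft.fft2(patch))
    if spec[0, 0] >= 0.5 * spec.sum():
        raise ValueError("DC-dominated filter; Gabor characterization undefined")

    p0 = np.array(_initial_gabor_guess(patch))
    lower = [0.0, -patch_size, -patch_size, 0.3, 0.3, 1e-3, -np.pi, -2 * np.pi]
    upper = [10 * np.abs(patch).max() + 1e-9, 2 * patch_size, 2 * patch_size,
             4 * patch_size, 4 * patch_size, np.sqrt(2) / 2, 2 * np.pi,
             2 * np.pi]
    p0 = np.clip(p0, lower, upper)

    def residual(p):
        return (gabor_patch(patch_size, *p) - patch).ravel()

    try:
        res = optimize.least_squares(residual, p0, bounds=(lower, upper),
                                     max_nfev=2000)
    except Exception:
        return GaborParams(np.nan, np.nan, np.nan, np.inf)
    if not np.all(np.isfinite(res.x)):
        return GaborParams(np.nan, np.nan, np.nan, np.inf)
    amp, x0, y0, sx, sy, f0, theta, phase = res.x
    rel_resid = float(np.linalg.norm(res.fun) / norm)
    orientation = float(np.degrees(theta % np.pi))
    bw = gabor_half_amplitude_bandwidth(f0, sx)
    return GaborParams(center_frequency=float(f0), orientation=orientation,
                       bandwidth=bw, fit_residual=rel_resid)


def characterize_bank(bank: FilterBank) -> pd.DataFrame:
    """Gabor characterization table, one row per non-DC filter.

    Columns: filter index, center_frequency (cycles/pixel), orientation
    (degrees), bandwidth (octaves), fit_residual.
    """
    rows = []
    for k in range(bank.n_filters):
        if k == bank.dc_index:
            continue
        params = fit_gabor(bank.filters[k], bank.patch_size)
        rows.append({"filter": k, **dataclasses.asdict(params)})
    return pd.DataFrame(
        rows, columns=["filter", "center_frequency", "orientation",
                       "bandwidth", "fit_residual"])


def bank_summary(table: pd.DataFrame, bandwidth_bin_width: float = 0.1,
                 frequency_split: float = 0.25) -> dict:
    """Summary statistics of a characterization table.

    Reports the fraction of filters whose preferred frequency exceeds
    ``frequency_split`` cycles/pixel and the histogram of finite
    half-amplitude bandwidths (bin edges at multiples of
    ``bandwidth_bin_width`` octaves), including the mode bin.
    """
    if table.empty:
        return {"n_filters": 0, "fraction_high_frequency": np.nan,
                "bandwidth_hist": np.array([]),
                "bandwidth_bin_edges": np.array([]),
                "bandwidth_mode_bin": (np.nan, np.nan)}
    freqs = table["center_frequency"].to_numpy()
    frac_high = float(np.mean(freqs > frequency_split))
    bw = table["bandwidth"].to_numpy()
    bw = bw[np.isfinite(bw)]
    if bw.size == 0:
        return {"n_filters": len(table), "fraction_high_frequency": frac_high,
                "bandwidth_hist": np.array([]),
                "bandwidth_bin_edges": np.array([]),
                "bandwidth_mode_bin": (np.nan, np.nan)}
    n_bins = int(np.ceil(bw.max() / bandwidth_bin_width)) or 1
    edges = np.arange(n_bins + 1) * bandwidth_bin_width
    hist, _ = np.histogram(bw, bins=edges)
    mode = int(np.argmax(hist))
    return {
        "n_filters": len(table),
        "fraction_high_frequency": frac_high,
        "bandwidth_hist": hist,
        "bandwidth_bin_edges": edges,
        "bandwidth_mode_bin": (float(edges[mode]), float(edges[mode + 1])),
    }
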