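"""Synthetic stimuli, scenes, corpora and simulated participants.

Everything the package needs that would otherwise come from
photographs or a human experiment is generated here, deterministically
per seed:

* luminance-step edge patches and two-dimensional cosine gratings —
  the control stimuli for the contrast and kurtosis machinery;
* "streetscape surrogate" scenes with a construction-defined
  complexity level (counts of high-contrast objects, area of smooth
  low-frequency regions over a textured ground);
* a textured image corpus with approximately 1/f amplitude spectra,
  suitable for learning IC filter banks without downloading a
  photographic database;
* simulated participants who rank items around a known true order
  with Gaussian rank jitter.

All stochastic outputs use ``numpy.random.default_rng`` seeded
explicitly, and images are integer-valued, so fixtures are
byte-identical across platforms for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ranking import SubjectRanking


@dataclass
class SurrogateScene:
    """A synthetic scene with recorded construction parameters."""

    image: np.ndarray
    n_objects: int
    smooth_fraction: float
    texture_freq: float
    seed: int

    @property
    def complexity(self) -> float:
        """Construction-defined complexity: object count plus smooth area."""
        return self.n_objects + 10.0 * self.smooth_fraction


def make_edge(size: int = 16, delta: float = 128) -> np.ndarray:
    """A luminance-step edge patch: bright upper half, dark lower half.

    Exactly two luminance values, centered in [0, 255] and differing by
    ``delta``, so the patch RMS contrast is exactly delta/2.
    """
    if not 0 <= delta <= 255:
        raise ValueError(f"delta must be in [0, 255], got {delta}")
    lower = round((255 - delta) / 2)
    upper = lower + delta
    patch = np.full((size, size), lower, dtype=float)
    patch[: size // 2, :] = upper
    return patch


def make_grating(size: int = 16, frequency: float = 0.25) -> np.ndarray:
    """A two-dimensional cosine grating with equal h/v frequency components.

    ``cos(2*pi*f*(u + v))`` scaled to [0, 255]; the spectral peak sits
    at (f, f), i.e. a 45-degree oriented grating.  ``f = 0.5`` gives the
    alternating diagonal Nyquist pattern.
    """
    if not 0 < frequency <= 0.5:
        raise ValueError(f"frequency must be in (0, 0.5] cycles/pixel, got {frequency}")
    v, u = np.mgrid[0:size, 0:size].astype(float)
    return 127.5 * (1.0 + np.cos(2 * np.pi * frequency * (u + v)))


def _blob_mask(shape, fraction, rng, blur: float = 8.0) -> np.ndarray:
    """Random smooth blobs covering approximately ``fraction`` of the image."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    if fraction >= 1:
        return np.ones(shape, dtype=bool)
    field = ndimage.gaussian_filter(rng.standard_normal(shape), blur)
    thresh = np.quantile(field, 1.0 - fraction)
    return field >= thresh


def _bandpass_texture(shape, frequency, rng, bandwidth: float = 0.1) -> np.ndarray:
    """Unit-variance isotropic band-pass noise centered at ``frequency`` cpp."""
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])
    fx = np.fft.fftfreq(shape[1])
    r = np.hypot(fy[:, None], fx[None, :])
    gain = np.exp(-((r - frequency) ** 2) / (2 * bandwidth ** 2))
    tex = np.real(np.fft.ifft2(np.fft.fft2(white) * gain))
    sd = tex.std()
    return tex / sd if sd > 0 else tex


def make_surrogate_scene(n_objects: int = 5, smooth_fraction: float = 0.2,
                         texture_freq: float = 0.3, size: int = 256,
                         seed: int = 0) -> SurrogateScene:
    """A synthetic stand-in for a streetscape photograph.

    A mid-gray canvas carries fine texture everywhere (band-pass noise
    at ``texture_freq`` cycles/pixel), smooth low-frequency regions
    (heavily blurred luminance blobs) over ``smooth_fraction`` of the
    area, and ``n_objects`` high-contrast rectangles.  More objects
    raise the mean local contrast; more smooth area skews the
    kurtosis-map distribution towards high values.
    """
    if n_objects < 0:
        raise ValueError("n_objects must be nonnegative")
    if not 0 <= smooth_fraction <= 1:
        raise ValueError("smooth_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    img = np.full((size, size), 128.0)
    img += 12.0 * _bandpass_texture((size, size), texture_freq, rng)

    smooth = ndimage.gaussian_filter(rng.standard_normal((size, size)), 16.0)
    sd = smooth.std()
    if sd > 0:
        smooth = 128.0 + 35.0 * smooth / sd
    else:
        smooth = np.full((size, size), 128.0)
    mask = _blob_mask((size, size), smooth_fraction, rng)
    img[mask] = smooth[mask]

    for k in range(n_objects):
        h = int(rng.integers(8, 25))
        w = int(rng.integers(8, 25))
        i = int(rng.integers(0, size - h))
        j = int(rng.integers(0, size - w))
        value = 235.0 if k % 2 == 0 else 20.0
        img[i:i + h, j:j + w] = value

    img = np.clip(np.rint(img), 0, 255)
    return SurrogateScene(image=img, n_objects=n_objects,
                          smooth_fraction=smooth_fraction,
                          texture_freq=texture_freq, seed=seed)


def _dead_leaves(size: int, rng, n_shapes: int, r_min: float, r_max: float,
                 bar_fraction: float, blur: float, noise: float) -> np.ndarray:
    """Occlusion ("dead leaves") texture: disks and oriented bars.

    Shape radii follow a power law (density ~ r^-3), the classic
    scale-invariant occlusion model, which yields an approximately 1/f
    amplitude spectrum and the sparse, edge-dominated higher-order
    statistics of photographs.
    """
    img = np.full((size, size), rng.uniform(60, 200))
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    for _ in range(n_shapes):
        u = rng.uniform()
        r = r_min / np.sqrt(1 - u * (1 - (r_min / r_max) ** 2))
        cy, cx = rng.uniform(0, size, 2)
        val = rng.uniform(0, 255)
        if rng.uniform() < bar_fraction:
            theta = rng.uniform(0, np.pi)
            dx = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
            dy = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
            mask = (np.abs(dx) < 3 * r) & (np.abs(dy) < max(1.0, r / 3))
        else:
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 < r ** 2
        img[mask] = val
    if blur > 0:
        img = ndimage.gaussian_filter(img, blur)
    if noise > 0:
        img += rng.normal(0, noise, (size, size))
    return img


def make_texture_corpus(n_images: int = 50, size: int = 256,
                        seed: int = 0) -> list:
    """Textured images with photograph-like statistics for ICA learning.

    Each image is a dead-leaves texture — occluding disks and oriented
    bars with power-law sizes — under mild optical blur and sensor
    noise, with a per-image exposure (gain/offset) spread emulating the
    luminance diversity of day and night scenes.  This reproduces the
    features ICA learning needs from photographs: an approximately 1/f
    amplitude spectrum, sparse non-Gaussian edge structure at all
    orientations, and structured energy up to the Nyquist frequency.
    Integer-valued and deterministic per seed.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    ss = np.random.SeedSequence(seed)
    n_shapes = max(1, round(880 * (size / 256) ** 2))
    r_max = min(60.0, size / 2)
    out = []
    for child in ss.spawn(n_images):
        rng = np.random.default_rng(child)
        img = _dead_leaves(size, rng, n_shapes=n_shapes, r_min=2.0,
                           r_max=r_max, bar_fraction=0.3, blur=0.7,
                           noise=1.5)
        gain = rng.uniform(0.35, 1.0)
        img = img * gain + rng.uniform(0, 40)
        out.append(np.clip(np.rint(img), 0, 255))
    return out


def make_participants(true_order, noise_sigma: float = 2.0,
                      n_subjects: int = 40,
                      group_quantiles: tuple = (12 / 74, 59 / 74),
                      seed: int = 0) -> list:
    """Simulated participants ranking items around a known true order.

    Each subject perturbs the true-order positions with Gaussian jitter
    of ``noise_sigma`` rank positions, sorts by the jittered scores, and
    splits the result into simple/ordinary/complex groups at the given
    quantiles (defaults mirror a 74-item session splitting 12/47/15).
    Zero noise reproduces the true order for every subject.
    """
    items = list(true_order)
    n = len(items)
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    q1, q2 = group_quantiles
    if not 0 <= q1 <= q2 <= 1:
        raise ValueError("group quantiles must satisfy 0 <= q1 <= q2 <= 1")
    n1 = int(round(q1 * n))
    n2 = int(round(q2 * n))
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_subjects):
        scores = np.arange(n) + noise_sigma * rng.standard_normal(n)
        order = [items[i] for i in np.argsort(scores, kind="stable")]
        out.append(SubjectRanking(subject_id=f"s{s:02d}", simple=order[:n1],
                                  ordinary=order[n1:n2], complex=order[n2:]))
    return out
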