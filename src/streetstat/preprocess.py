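"""Image loading and presentation preprocessing.

Photographs are collapsed to a single luminance channel, anti-alias
filtered and decimated to display resolution, and quantized to 8-bit
integer luminance in [0, 255].  Decimation uses a zero-phase
eighth-order Chebyshev Type I low-pass (applied forward-backward along
each axis) followed by subsampling, the classic anti-aliased
"decimate" construction.

Small viewing-geometry helpers convert between pixel counts, physical
display size and visual angle, so that spatial frequencies can be
expressed in cycles/degree for a given presentation setup.
"""

from __future__ import annotations

import math

import imageio.v3 as iio
import numpy as np
from scipy import signal

#: Rec. 601 luma weights, available as an alternative channel collapse.
REC601_WEIGHTS = (0.299, 0.587, 0.114)


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster as a numpy array.

    Returns a 2-D array for single-channel files and an H x W x 3 array
    for color files (an alpha channel, if present, is dropped).  Values
    are preserved at the file's native scale; 16-bit TIFFs keep their
    16-bit range until :func:`quantize_8bit`.

    Raises
    ------
    OSError
        If the file is missing, truncated or not a supported raster.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises plugin-specific types
        raise OSError(f"cannot read raster image {str(path)!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3):
        raise OSError(f"{str(path)!r} is not a 2-D raster image")
    return arr


def to_grayscale(img: np.ndarray, weights=None) -> np.ndarray:
    """Collapse an H x W x 3 color image to one luminance channel.

    The default collapse is the unweighted mean of the three channels;
    pass ``weights`` (e.g. :data:`REC601_WEIGHTS`) for a weighted luma.
    2-D input is returned unchanged (already grayscale).
    """
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 color image, got shape {img.shape}")
    if weights is None:
        return img.mean(axis=2)
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValueError("weights must be a length-3 sequence")
    return img @ (w / w.sum())


def design_lowpass(factor: int, cutoff: float | None = None,
                   ripple_db: float = 0.05, order: int = 8):
    """Anti-aliasing filter coefficients (b, a) for a decimation factor.

    Chebyshev Type I with `ripple_db` passband ripple and normalized
    cutoff ``0.8 / factor`` of Nyquist unless an explicit ``cutoff``
    (in (0, 1], Nyquist = 1) is given.
    """
    if cutoff is None:
        cutoff = 0.8 / factor
    if not 0 < cutoff <= 1:
        raise ValueError(f"normalized cutoff must be in (0, 1], got {cutoff}")
    return signal.cheby1(order, ripple_db, cutoff)


def zero_phase_lowpass(img: np.ndarray, factor: int,
                       cutoff: float | None = None,
                       ripple_db: float = 0.05) -> np.ndarray:
    """The anti-aliasing stage of :func:`decimate`, before subsampling.

    Applies the Chebyshev low-pass forward and backward (zero phase)
    separably along rows then columns.  Edge transients are handled
    with Gustafsson's method, which makes the result invariant to time
    reversal — an even-symmetric input therefore yields an exactly
    symmetric output, the defining zero-phase property.  Exposed so
    the filtered signal can be inspected at full resolution.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    b, a = design_lowpass(factor, cutoff=cutoff, ripple_db=ripple_db)
    x = img
    for axis in (0, 1):
        x = signal.filtfilt(b, a, x, axis=axis, method="gust")
    return x


def decimate(img: np.ndarray, factor: int, cutoff: float | None = None,
             ripple_db: float = 0.05) -> np.ndarray:
    """Low-pass filter and downsample a grayscale image by ``factor``.

    Anti-aliasing via :func:`zero_phase_lowpass`, then subsampling so
    each output dimension is ``floor(dim / factor)``.  ``factor=1``
    returns a float copy unchanged.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("decimate expects a 2-D grayscale image")
    if not (isinstance(factor, (int, np.integer)) and factor >= 1):
        raise ValueError(f"decimation factor must be a positive integer, got {factor}")
    if min(img.shape) < 2 * factor:
        raise ValueError(
            f"image {img.shape} too small to decimate by {factor}")
    if factor == 1:
        return img.copy()
    x = zero_phase_lowpass(img, factor, cutoff=cutoff, ripple_db=ripple_db)
    h, w = img.shape
    return x[::factor, ::factor][: h // factor, : w // factor]


def quantize_8bit(img: np.ndarray, source_depth: int = 8) -> np.ndarray:
    """Map a real-valued image to 8-bit integers in [0, 255].

    Values are scaled linearly from the source bit-depth full range
    ``[0, 2**source_depth - 1]`` to [0, 255], rounded half-to-even, and
    clipped.  Small filtering overshoot (negative or above-full-scale
    values) is clipped rather than rescaled.
    """
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains NaN or infinite values")
    if source_depth < 1:
        raise ValueError("source_depth must be >= 1")
    scale = 255.0 / (2 ** source_depth - 1)
    return np.clip(np.rint(img * scale), 0, 255).astype(np.uint8)


def visual_angle_deg(n_pixels: int, pixel_pitch_mm: float,
                     viewing_distance_cm: float) -> float:
    """Visual angle (degrees) subtended by ``n_pixels`` on a display.

    Uses the full-angle formula ``2 * atan(extent / 2 / distance)`` with
    the physical extent ``n_pixels * pixel_pitch_mm``.
    """
    extent_mm = n_pixels * pixel_pitch_mm
    return math.degrees(2 * math.atan(extent_mm / 2 / (viewing_distance_cm * 10)))


def nyquist_cycles_per_degree(n_pixels: int, angle_deg: float) -> float:
    """Maximum representable spatial frequency in cycles/degree.

    ``n_pixels`` spanning ``angle_deg`` degrees sample at
    ``n_pixels / angle_deg`` pixels/degree, so the Nyquist limit is half
    that in cycles/degree.
    """
    return n_pixels / angle_deg / 2
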