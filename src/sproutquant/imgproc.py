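"""Low-level image operators composed by the mask pipeline.

All operators take and return 2-D float arrays normalized to [0, 1]
(``Image2D``) or boolean arrays of the same shape (``BinaryMask``), and all
preserve raster shape.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, signal
from skimage import exposure

log = logging.getLogger(__name__)

__all__ = [
    "median_smooth",
    "equalize_adaptive",
    "sobel_edge_mask",
    "gaussian_spread",
    "nonzero_stats_threshold",
    "gaussian_kernel",
]


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a nonempty 2-D image, got shape {img.shape}")
    return img


def median_smooth(img: np.ndarray, kernel: int = 1) -> np.ndarray:
    """Median filter with a square ``kernel`` x ``kernel`` window.

    Borders are edge-replicated. ``kernel=1`` is the identity.
    """
    img = _check_image(img)
    if not isinstance(kernel, (int, np.integer)) or kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be a positive odd integer, got {kernel!r}")
    if kernel == 1:
        return img.copy()
    return ndimage.median_filter(img, size=kernel, mode="nearest")


def equalize_adaptive(
    img: np.ndarray, tiles: tuple[int, int] = (8, 8), clip: float = 0.01
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    The image is divided into a ``tiles`` grid; each tile's histogram is
    clipped at ``clip`` and equalized, and tile mappings are bilinearly
    interpolated. Output is in [0, 1]. A flat image is returned unchanged
    (its histogram carries no contrast to redistribute).
    """
    img = _check_image(img)
    if any(t < 1 for t in tiles):
        raise ValueError(f"tiles must be >= 1 in each axis, got {tiles!r}")
    if img.max() == img.min():
        return img.copy()
    kernel_size = (
        max(1, img.shape[0] // int(tiles[0])),
        max(1, img.shape[1] // int(tiles[1])),
    )
    out = exposure.equalize_adapthist(
        np.clip(img, 0.0, 1.0), kernel_size=kernel_size, clip_limit=clip
    )
    return np.clip(out, 0.0, 1.0)


def sobel_edge_mask(img: np.ndarray, sensitivity: float = 1.0) -> np.ndarray:
    """Binary edge mask from the Sobel gradient magnitude.

    The magnitude combines 3x3 Sobel responses along both axes and is
    binarized at ``sensitivity * RMS(magnitude)``, a scale-invariant
    automatic threshold: multiplying the image by a constant leaves the
    mask unchanged. A constant image yields an empty mask.
    """
    img = _check_image(img)
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    from skimage import filters

    grad = filters.sobel(img)
    rms = float(np.sqrt(np.mean(grad**2)))
    return grad > sensitivity * rms


def gaussian_kernel(width: int, sigma: float) -> np.ndarray:
    """Square ``width`` x ``width`` Gaussian kernel normalized to unit sum."""
    if width < 1:
        raise ValueError("width must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    # symmetric offsets; for even width the grid straddles the mode
    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    g = np.exp(-(offsets**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def gaussian_spread(mask: np.ndarray, width: int = 100, sigma: float | None = None) -> np.ndarray:
    """Spread a binary mask by linear convolution with a Gaussian kernel.

    This is the "dilation by convolution" step that closes the edge mask of
    the spheroid into a filled, blurred region. The mask is treated as 0/1
    reals, borders are zero-padded, and the kernel has unit sum, so the
    total mass equals the foreground count up to border truncation.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError(f"expected a nonempty 2-D mask, got shape {mask.shape}")
    if sigma is None:
        sigma = width / 5.0
    if not mask.any():
        return np.zeros(mask.shape, dtype=float)
    k = gaussian_kernel(width, sigma)
    out = signal.fftconvolve(mask.astype(float), k, mode="same")
    # FFT round-off can leave tiny negatives
    np.maximum(out, 0.0, out=out)
    return out


def nonzero_stats_threshold(
    img: np.ndarray, coeff: float = 0.3
) -> tuple[float, np.ndarray]:
    """Threshold an image at ``median(nonzero) + coeff * SD(nonzero)``.

    The statistics are computed over the nonzero pixels only (the zero
    background would otherwise dominate the median); the SD uses the sample
    (N-1) denominator. Pixels strictly greater than the threshold form the
    mask, so a flat nonzero plateau yields an empty mask.

    Returns ``(threshold, mask)``. An all-zero image returns ``(0.0,
    empty mask)`` with a warning, since there is no nonzero population.
    """
    img = _check_image(img)
    if coeff < 0:
        raise ValueError("coeff must be >= 0")
    nz = img[img != 0]
    if nz.size == 0:
        log.warning("nonzero_stats_threshold: image has no nonzero pixels; returning empty mask")
        return 0.0, np.zeros(img.shape, dtype=bool)
    med = float(np.median(nz))
    sd = float(np.std(nz, ddof=1)) if nz.size > 1 else 0.0
    t = med + coeff * sd
    return t, img > t
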