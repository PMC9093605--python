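"""Segmentation masks: total spheroid, spheroid center, and sprouting area.

The total spheroid mask is segmented from edges: median smoothing, adaptive
histogram equalization, Sobel edge detection, Gaussian-convolution spreading,
and a median + coeff*SD threshold over the nonzero pixels. The center is the
brightest region of the (separately smoothed) raw image, dilated to cover the
body's dim rim. The sprouting area is the set difference total \\ center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .config import PipelineConfig
from .imgproc import (
    equalize_adaptive,
    gaussian_spread,
    median_smooth,
    nonzero_stats_threshold,
    sobel_edge_mask,
)

log = logging.getLogger(__name__)

__all__ = ["MaskSet", "total_spheroid_mask", "center_mask", "sprout_area_mask", "build_masks"]


@dataclass(frozen=True)
class MaskSet:
    """The three aligned masks of one spheroid image plus the threshold used.

    Invariants (checked on construction): ``center`` is a subset of
    ``total``, ``sprout_area`` equals ``total`` minus ``center``, and the
    pixel counts add up.
    """

    total: np.ndarray
    center: np.ndarray
    sprout_area: np.ndarray
    threshold_value: float

    def __post_init__(self) -> None:
        if not (self.total.shape == self.center.shape == self.sprout_area.shape):
            raise ValueError("mask shapes differ")
        if np.any(self.center & ~self.total):
            raise ValueError("center mask is not contained in total mask")
        if np.any(self.sprout_area != (self.total & ~self.center)):
            raise ValueError("sprout_area is not total \\ center")


def _largest_component(mask: np.ndarray, connectivity: int) -> np.ndarray:
    if not mask.any():
        return mask
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndimage.label(mask, structure=structure)
    if n <= 1:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(sizes.argmax())


def total_spheroid_mask(
    img: np.ndarray, cfg: PipelineConfig | None = None
) -> tuple[np.ndarray, float]:
    """Segment the total spheroid area (body plus attached sprouts).

    Returns ``(mask, threshold)``. A blank image (no detectable edges)
    yields an empty mask and threshold 0 with a warning; downstream metrics
    are then zero.
    """
    cfg = cfg or PipelineConfig()
    smoothed = median_smooth(img, cfg.noise_median_kernel)
    equalized = equalize_adaptive(smoothed, cfg.clahe_tiles, cfg.clahe_clip)
    edges = sobel_edge_mask(equalized, cfg.sobel_sensitivity)
    spread = gaussian_spread(edges, cfg.gauss_width, cfg.gauss_sigma_resolved)
    threshold, mask = nonzero_stats_threshold(spread, cfg.threshold_coeff)
    if not mask.any():
        log.warning("total_spheroid_mask: no foreground segmented; image may be blank")
        return mask, threshold
    if cfg.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if cfg.keep_largest_component:
        mask = _largest_component(mask, cfg.connectivity)
    return mask, threshold


def center_mask(
    img: np.ndarray, total: np.ndarray, cfg: PipelineConfig | None = None
) -> np.ndarray:
    """Detect the spheroid center (the cell body) as the brightest region.

    The raw image is median-smoothed, pixels at or above
    ``center_bright_fraction`` of the smoothed maximum are selected, the
    largest connected region is kept, dilated by a disk of
    ``center_dilate_radius``, and intersected with ``total``.
    """
    cfg = cfg or PipelineConfig()
    img = np.asarray(img, dtype=float)
    if img.shape != total.shape:
        raise ValueError("image and total mask shapes differ")
    if not total.any():
        return np.zeros_like(total, dtype=bool)
    smoothed = median_smooth(img, cfg.center_median_kernel)
    peak = smoothed.max()
    if peak <= 0:
        return np.zeros_like(total, dtype=bool)
    bright = smoothed >= cfg.center_bright_fraction * peak
    bright = _largest_component(bright, cfg.connectivity)
    dilated = morphology.dilation(bright, morphology.disk(cfg.center_dilate_radius))
    return dilated & total


def sprout_area_mask(total: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Sprouting area = total spheroid area minus the spheroid center."""
    if total.shape != center.shape:
        raise ValueError("total and center mask shapes differ")
    if np.any(center & ~total):
        raise ValueError("center mask is not contained in total mask")
    return total & ~center


def build_masks(img: np.ndarray, cfg: PipelineConfig | None = None) -> MaskSet:
    """Run the full mask pipeline on one normalized image."""
    cfg = cfg or PipelineConfig()
    total, threshold = total_spheroid_mask(img, cfg)
    center = center_mask(img, total, cfg)
    sprout = sprout_area_mask(total, center)
    return MaskSet(total=total, center=center, sprout_area=sprout, threshold_value=threshold)
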