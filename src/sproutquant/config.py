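"""Pipeline configuration.

All numeric constants of the mask and skeleton pipelines live here so that a
single frozen object fully determines a run. Defaults reproduce the published
processing chain for spheroid sprouting images acquired at 2 um/px; every
value is overridable for other acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Any


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the sprout-quantification pipeline.

    Parameters
    ----------
    noise_median_kernel:
        Side of the square median filter applied before contrast
        enhancement, in pixels (odd). The default of 1 is the identity:
        the reference acquisition needs no denoising beyond it.
    clahe_tiles:
        Tile grid (rows, cols) of the contrast-limited adaptive histogram
        equalization used to bring dim sprouts up before edge detection.
    clahe_clip:
        CLAHE clip limit as a fraction of the per-tile histogram.
    sobel_sensitivity:
        The Sobel gradient magnitude is binarized at
        ``sensitivity * RMS(gradient)``, a scale-invariant automatic edge
        threshold. The default of 3 keeps the contiguous gradient ridges of
        real structures while rejecting isolated noise responses; 1 marks
        roughly everything above the average gradient and is far too
        permissive on noisy backgrounds.
    gauss_width:
        Support of the square Gaussian kernel (pixels) convolved with the
        edge mask to close the spheroid body into a filled region.
    gauss_sigma:
        Standard deviation of that kernel in pixels; ``None`` resolves to
        ``gauss_width / 5``. The default of 3 px closes the paired side
        edges of a sprout into one solid ribbon without fusing adjacent
        sprouts, which larger blurs do (two sprouts 30-50 px apart merge
        already at sigma near 10, and the skeleton then traces the merged
        blob instead of the sprouts); calibrated on synthetic ground
        truth.
    threshold_coeff:
        The convolved edge image is thresholded at
        ``median(nonzero) + threshold_coeff * SD(nonzero)``; 0.3 was
        determined empirically for this assay.
    center_median_kernel:
        Side of the median filter (odd, pixels) smoothing the raw image
        before the brightest-pixel center detection.
    center_bright_fraction:
        Pixels at or above this fraction of the smoothed maximum seed the
        spheroid-center mask.
    center_dilate_radius:
        Disk radius (pixels) by which the detected center is dilated to
        cover the dim rim of the spheroid body.
    skeleton_min_branch:
        Minimum branch length (pixels) kept in the initial skeleton;
        1 keeps every branch.
    refine_prune_px:
        Minimum branch length (pixels) kept when the skeleton is rebuilt
        after center subtraction and diamond dilation; removes thinning
        spurs shorter than real sprouts.
    diamond_radius:
        Radius of the diamond (L1-ball) structuring element used to
        reconnect skeleton fragments after center subtraction.
    min_component_px:
        Connected skeletal components smaller than this many pixels are
        discarded as noise; components of exactly this size are kept.
    attach_tolerance_px:
        A skeletal component within this many pixels of the center mask is
        classified attached. Must exceed ``diamond_radius`` (re-thinning
        after the diamond dilation retracts free ends by up to that much)
        plus a pixel or two of segmentation erosion where a sprout neck
        meets the bright body; it must stay far below the distance at
        which genuinely migrated fragments occur (tens of pixels).
    connectivity:
        Pixel connectivity for component analysis, 4 or 8.
    pixel_size_um:
        Physical pixel size in micrometres, used only to convert the
        cumulative sprout length from pixels to um.
    fill_holes / keep_largest_component:
        Post-processing of the total spheroid mask: fill enclosed holes
        (the body is solid tissue) and drop fragments of neighboring
        spheroids caught at crop borders.
    plane_index:
        Which page of a multi-page TIFF to analyze (single focal plane).
    """

    noise_median_kernel: int = 1
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip: float = 0.01
    sobel_sensitivity: float = 3.0
    gauss_width: int = 100
    gauss_sigma: float | None = 3.0
    threshold_coeff: float = 0.3
    center_median_kernel: int = 11
    center_bright_fraction: float = 0.90
    center_dilate_radius: int = 5
    skeleton_min_branch: int = 1
    refine_prune_px: int = 10
    diamond_radius: int = 2
    min_component_px: int = 6
    attach_tolerance_px: int = 5
    connectivity: int = 8
    pixel_size_um: float = 2.0
    fill_holes: bool = True
    keep_largest_component: bool = False
    plane_index: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_median_kernel", "center_median_kernel"):
            k = getattr(self, name)
            if not isinstance(k, int) or k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be a positive odd integer, got {k!r}")
        if len(self.clahe_tiles) != 2 or any(t < 1 for t in self.clahe_tiles):
            raise ValueError(f"clahe_tiles must be a pair of integers >= 1, got {self.clahe_tiles!r}")
        if not 0 < self.clahe_clip <= 1:
            raise ValueError("clahe_clip must be in (0, 1]")
        if self.sobel_sensitivity <= 0:
            raise ValueError("sobel_sensitivity must be positive")
        if self.gauss_width < 1:
            raise ValueError("gauss_width must be >= 1")
        if self.gauss_sigma is not None and self.gauss_sigma <= 0:
            raise ValueError("gauss_sigma must be positive")
        if self.threshold_coeff < 0:
            raise ValueError("threshold_coeff must be >= 0")
        if not 0 < self.center_bright_fraction <= 1:
            raise ValueError("center_bright_fraction must be in (0, 1]")
        for name in ("center_dilate_radius", "skeleton_min_branch", "refine_prune_px",
                     "diamond_radius", "min_component_px", "attach_tolerance_px"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.plane_index < 0:
            raise ValueError("plane_index must be >= 0")

    @property
    def gauss_sigma_resolved(self) -> float:
        """Effective Gaussian sigma in pixels (``gauss_width / 5`` if unset)."""
        return self.gauss_sigma if self.gauss_sigma is not None else self.gauss_width / 5.0

    def with_overrides(self, **kwargs: Any) -> "PipelineConfig":
        """Return a copy with the given fields replaced; unknown keys raise."""
        valid = {f.name for f in fields(self)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
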