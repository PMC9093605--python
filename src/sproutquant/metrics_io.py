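"""End-to-end per-image analysis, TIFF reading, cropping, and CSV output.

One image in, one :class:`SproutMetrics` record out; a directory of images
in, one metrics CSV out, with per-image failures logged and the batch
continuing. Intensities of integer TIFFs are normalized by the dtype
maximum (not the per-image maximum) so thresholds are comparable across
images of one acquisition.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import PipelineConfig
from .masks import build_masks
from .skeleton import (
    Attachment,
    classify_components,
    cumulative_sprout_length,
    filter_small_components,
    initial_skeleton,
    refine_skeleton,
    subtract_center,
)

log = logging.getLogger(__name__)

__all__ = [
    "SproutMetrics",
    "CropRect",
    "CSV_COLUMNS",
    "read_image",
    "write_metrics_csv",
    "read_metrics_csv",
    "read_crop_rects_csv",
    "crop_regions",
    "analyze_image",
    "analyze_arrays",
    "analyze_directory",
    "qc_overlay",
]

CSV_COLUMNS = [
    "image_id",
    "total_area_px",
    "sprout_area_px",
    "n_sprouts_total",
    "n_attached",
    "n_migrated",
    "csl_px",
    "csl_um",
    "threshold_value",
]


@dataclass(frozen=True)
class SproutMetrics:
    """Per-spheroid quantification record (one CSV row)."""

    image_id: str
    total_area_px: int
    sprout_area_px: int
    n_sprouts_total: int
    n_attached: int
    n_migrated: int
    csl_px: int
    csl_um: float
    threshold_value: float

    def __post_init__(self) -> None:
        if self.n_sprouts_total != self.n_attached + self.n_migrated:
            raise ValueError("n_sprouts_total must equal n_attached + n_migrated")
        if self.sprout_area_px > self.total_area_px:
            raise ValueError("sprout_area_px cannot exceed total_area_px")
        if min(self.total_area_px, self.sprout_area_px, self.n_attached,
               self.n_migrated, self.csl_px) < 0:
            raise ValueError("counts and areas must be nonnegative")


@dataclass(frozen=True)
class CropRect:
    """A crop rectangle on a stitched well image.

    Coordinates are 0-based with top-left origin; the rectangle spans the
    half-open ranges ``[row0, row0 + height)`` x ``[col0, col0 + width)``.
    """

    image_id: str
    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError(f"crop '{self.image_id}': height and width must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError(f"crop '{self.image_id}': origin must be nonnegative")


def _normalize(arr: np.ndarray, path: str | Path = "<array>") -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError(f"{path}: RGB(A) images are not supported; provide single-channel")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D plane, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(float)
        if out.size and (np.nanmax(out) > 1.0 or np.nanmin(out) < 0.0):
            raise ValueError(f"{path}: float images must already be normalized to [0, 1]")
        return np.nan_to_num(out, nan=0.0)
    raise ValueError(f"{path}: unsupported bit depth {arr.dtype}; expected uint8/uint16/float")


def read_image(path: str | Path, plane: int = 0) -> np.ndarray:
    """Read one focal plane of a grayscale TIFF, normalized to [0, 1].

    Multi-page files use page ``plane`` (never a maximum-intensity
    projection, which smears the spheroid's halo over the sprouts).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        if tif.pages[0].samplesperpixel > 1:
            raise ValueError(f"{path}: RGB(A) images are not supported; provide single-channel")
        arr = tif.asarray()
    if arr.ndim == 3:  # z-stack: pages or a volumetric series
        if plane >= arr.shape[0]:
            raise ValueError(f"{path}: plane {plane} requested but file has {arr.shape[0]} plane(s)")
        arr = arr[plane]
    elif plane > 0:
        raise ValueError(f"{path}: plane {plane} requested but file has 1 plane")
    return _normalize(arr, path)


def crop_regions(
    well_img: np.ndarray, rects: list[CropRect]
) -> list[tuple[str, np.ndarray]]:
    """Extract sub-rasters for each rectangle; cropping is lossless."""
    out = []
    for rect in rects:
        r1, c1 = rect.row0 + rect.height, rect.col0 + rect.width
        if r1 > well_img.shape[0] or c1 > well_img.shape[1]:
            raise ValueError(
                f"crop '{rect.image_id}' exceeds the well image "
                f"({well_img.shape[0]}x{well_img.shape[1]})"
            )
        out.append((rect.image_id, well_img[rect.row0:r1, rect.col0:c1].copy()))
    return out


def read_crop_rects_csv(path: str | Path) -> list[CropRect]:
    """Read crop rectangles from a CSV with header image_id,row0,col0,height,width."""
    df = pd.read_csv(path)
    required = ["image_id", "row0", "col0", "height", "width"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        CropRect(
            image_id=str(row.image_id),
            row0=int(row.row0),
            col0=int(row.col0),
            height=int(row.height),
            width=int(row.width),
        )
        for row in df.itertuples()
    ]


def analyze_image(
    img: np.ndarray, cfg: PipelineConfig | None = None, image_id: str = "image"
) -> SproutMetrics:
    """Run the full mask + skeleton pipeline on one normalized image.

    Degenerate inputs (blank well, core with no sprouts) produce zeroed
    metrics with a warning rather than an error.
    """
    cfg = cfg or PipelineConfig()
    maskset = build_masks(img, cfg)
    skel0 = initial_skeleton(maskset.total, cfg)
    raw = subtract_center(skel0, maskset.center)
    refined = refine_skeleton(raw, cfg)
    final = filter_small_components(refined, cfg)
    components = classify_components(final, maskset.center, cfg)
    n_attached = sum(1 for c in components if c.attachment is Attachment.ATTACHED)
    n_migrated = len(components) - n_attached
    csl_px, csl_um = cumulative_sprout_length(final, cfg)
    if not maskset.total.any():
        log.warning("analyze_image(%s): no spheroid detected; metrics are zero", image_id)
    elif not components:
        log.warning("analyze_image(%s): spheroid body found but no sprouts detected", image_id)
    return SproutMetrics(
        image_id=image_id,
        total_area_px=int(np.count_nonzero(maskset.total)),
        sprout_area_px=int(np.count_nonzero(maskset.sprout_area)),
        n_sprouts_total=len(components),
        n_attached=n_attached,
        n_migrated=n_migrated,
        csl_px=csl_px,
        csl_um=csl_um,
        threshold_value=float(maskset.threshold_value),
    )


def analyze_arrays(
    images: dict[str, np.ndarray], cfg: PipelineConfig | None = None
) -> list[SproutMetrics]:
    """Analyze a mapping of image_id -> normalized array, sorted by id."""
    return [analyze_image(images[k], cfg, k) for k in sorted(images)]


def analyze_directory(
    input_dir: str | Path,
    cfg: PipelineConfig | None = None,
    qc_dir: str | Path | None = None,
) -> tuple[list[SproutMetrics], dict[str, str]]:
    """Analyze every TIFF in a directory.

    Returns ``(records, errors)`` where ``errors`` maps failed file stems
    to messages; per-image failures never abort the batch. Records are
    sorted by image_id, so the result is independent of directory order.
    """
    cfg = cfg or PipelineConfig()
    input_dir = Path(input_dir)
    paths = sorted(p for p in input_dir.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
    records: list[SproutMetrics] = []
    errors: dict[str, str] = {}
    for path in paths:
        image_id = path.stem
        try:
            img = read_image(path, plane=cfg.plane_index)
            rec = analyze_image(img, cfg, image_id)
            records.append(rec)
            if qc_dir is not None:
                _write_qc(img, cfg, Path(qc_dir), image_id)
        except Exception as exc:  # noqa: BLE001 - batch robustness contract
            log.error("failed to analyze %s: %s", path.name, exc)
            errors[image_id] = str(exc)
    records.sort(key=lambda r: r.image_id)
    return records, errors


def write_metrics_csv(records: list[SproutMetrics], path: str | Path) -> None:
    """Write metrics to CSV with a fixed header, sorted by image_id."""
    df = pd.DataFrame([asdict(r) for r in records], columns=CSV_COLUMNS)
    df = df.sort_values("image_id") if len(df) else df
    df.to_csv(path, index=False, lineterminator="\n")


def read_metrics_csv(path: str | Path) -> list[SproutMetrics]:
    """Read a metrics CSV back into records (round-trips write_metrics_csv)."""
    df = pd.read_csv(path)
    return [
        SproutMetrics(
            image_id=str(row.image_id),
            total_area_px=int(row.total_area_px),
            sprout_area_px=int(row.sprout_area_px),
            n_sprouts_total=int(row.n_sprouts_total),
            n_attached=int(row.n_attached),
            n_migrated=int(row.n_migrated),
            csl_px=int(row.csl_px),
            csl_um=float(row.csl_um),
            threshold_value=float(row.threshold_value),
        )
        for row in df.itertuples()
    ]


def qc_overlay(img: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Render an RGB audit image: total mask outline (red), center outline
    (blue), and final skeleton (green) over the original intensities."""
    from skimage import morphology as _m

    cfg = cfg or PipelineConfig()
    maskset = build_masks(img, cfg)
    skel = filter_small_components(
        refine_skeleton(subtract_center(initial_skeleton(maskset.total, cfg), maskset.center), cfg),
        cfg,
    )
    base = (np.clip(img, 0, 1) * 255).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)

    def outline(mask: np.ndarray) -> np.ndarray:
        return mask & ~_m.binary_erosion(mask, _m.disk(1))

    rgb[outline(maskset.total)] = (255, 64, 64)
    rgb[outline(maskset.center)] = (64, 64, 255)
    rgb[skel] = (64, 255, 64)
    return rgb


def _write_qc(img: np.ndarray, cfg: PipelineConfig, qc_dir: Path, image_id: str) -> None:
    import imageio.v3 as iio

    qc_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(qc_dir / f"{image_id}_qc.png", qc_overlay(img, cfg))
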