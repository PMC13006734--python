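"""Micromarker detection: contrast enhancement to size-filtered bounding boxes.

The detection pipeline mirrors the optical front end of a marker-based strain
sensor: contrast-limited adaptive histogram equalization, unsharp
masking + Gaussian blur + a 3x3 sharpening convolution, frame-border removal,
Otsu binarization, and connected-component extraction with an area filter.

Coordinate convention throughout: origin top-left, x right, y down, pixel
centers at integer coordinates; centroids are (cx, cy) = (column, row).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure
from skimage.measure import label as cc_label, regionprops

__all__ = [
    "DetectConfig",
    "BoundingBox",
    "MarkerSet",
    "enhance_contrast",
    "sharpen",
    "remove_border",
    "binarize",
    "otsu_threshold",
    "extract_markers",
    "detect_markers",
]

logger = logging.getLogger(__name__)


def _default_sharpen_kernel(center: float = 9.0) -> np.ndarray:
    k = -np.ones((3, 3))
    k[1, 1] = center
    return k


@dataclass
class DetectConfig:
    """Tunable parameters of the marker detection pipeline.

    ``clahe_clip`` follows the common OpenCV-style convention (contrast limit
    ~2.0); it is mapped internally to scikit-image's fractional clip limit.
    The sharpening kernel defaults to the standard -1-ring/+9-center form;
    an 11-center variant is selectable via ``sharpen_center``.
    """

    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    gaussian_sigma: float = 1.0
    sharpen_kernel: np.ndarray = field(default_factory=_default_sharpen_kernel)
    border_margin_px: int = 4
    min_area_px: float = 20.0
    max_area_px: float = 500.0

    def __post_init__(self) -> None:
        self.sharpen_kernel = np.asarray(self.sharpen_kernel, dtype=float)
        if not self.min_area_px < self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")
        if self.border_margin_px < 0:
            raise ValueError("border_margin_px must be >= 0")


@dataclass(frozen=True)
class BoundingBox:
    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError("box extents must be >= 1")


@dataclass
class MarkerSet:
    """Detected markers: sub-pixel centroids, boxes and pixel areas."""

    centroids: np.ndarray  # (N, 2) as (cx, cy)
    boxes: list[BoundingBox]
    areas: np.ndarray  # (N,)

    def __len__(self) -> int:
        return len(self.boxes)

    @classmethod
    def empty(cls) -> "MarkerSet":
        return cls(np.empty((0, 2)), [], np.empty((0,)))

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            {
                "id": i,
                "cx": self.centroids[i, 0],
                "cy": self.centroids[i, 1],
                "x": b.x,
                "y": b.y,
                "w": b.w,
                "h": b.h,
                "area": self.areas[i],
            }
            for i, b in enumerate(self.boxes)
        ]
        pd.DataFrame(rows, columns=["id", "cx", "cy", "x", "y", "w", "h", "area"]).to_csv(path, index=False)


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("expected a 2-D grayscale image")
    return img


def enhance_contrast(img: np.ndarray, cfg: DetectConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (tile-wise).

    Returns an 8-bit image of the same shape.  A constant image is returned
    unchanged (up to quantization) since there is no contrast to stretch.
    """
    cfg = cfg or DetectConfig()
    img = _check_image(img)
    if img.max() == img.min():
        return img.astype(np.uint8, copy=True)
    ty, tx = cfg.clahe_tiles
    kernel = (max(img.shape[0] // ty, 1), max(img.shape[1] // tx, 1))
    out = exposure.equalize_adapthist(
        img.astype(np.uint8), kernel_size=kernel, clip_limit=cfg.clahe_clip / 100.0
    )
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def sharpen(img: np.ndarray, cfg: DetectConfig | None = None) -> np.ndarray:
    """Unsharp masking, Gaussian blur, then 3x3 sharpening convolution.

    Border pixels use edge replication; output is clipped to [0, 255].
    """
    cfg = cfg or DetectConfig()
    img = _check_image(img).astype(float)
    if cfg.sharpen_kernel.shape != (3, 3):
        raise ValueError("sharpen kernel must be 3x3")
    blurred = ndimage.gaussian_filter(img, sigma=1.0, mode="nearest")
    unsharp = img + 1.0 * (img - blurred)
    denoised = ndimage.gaussian_filter(unsharp, sigma=cfg.gaussian_sigma, mode="nearest")
    out = ndimage.convolve(denoised, cfg.sharpen_kernel, mode="nearest")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def remove_border(img: np.ndarray, margin: int, background: int = 255) -> np.ndarray:
    """Overwrite a ``margin``-wide frame border with background (white).

    Suppresses the dark vignette ring that misaligned optics leave at the
    frame edge, which would otherwise produce spurious components.
    """
    img = _check_image(img)
    if margin == 0:
        return img.copy()
    if 2 * margin >= min(img.shape):
        raise ValueError("margin too large for image")
    out = img.copy()
    out[:margin, :] = background
    out[-margin:, :] = background
    out[:, :margin] = background
    out[:, -margin:] = background
    return out


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's threshold by exhaustive between-class-variance sweep.

    Returns the threshold ``t`` maximizing the between-class variance of the
    partition {intensity <= t} / {intensity > t}; smallest argmax on ties.
    """
    img = _check_image(img)
    hist = np.bincount(img.astype(np.uint8).ravel(), minlength=256).astype(float)
    n = hist.sum()
    w0 = np.cumsum(hist)  # class {<= t}
    w1 = n - w0
    csum = np.cumsum(hist * np.arange(256))
    total = csum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (total - csum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-1.0)
    return int(np.argmax(sigma_b))


def binarize(img: np.ndarray) -> np.ndarray:
    """Otsu binarization; dark markers map to foreground (True).

    A constant image admits no threshold and yields all-background with a
    logged warning.
    """
    img = _check_image(img)
    if img.max() == img.min():
        logger.warning("binarize: constant image, returning all background")
        return np.zeros(img.shape, dtype=bool)
    t = otsu_threshold(img)
    return img <= t


def extract_markers(
    binary: np.ndarray,
    cfg: DetectConfig | None = None,
    intensity: np.ndarray | None = None,
) -> MarkerSet:
    """Connected foreground components to size-filtered marker records.

    Components use 8-connectivity (circular blobs must not split on
    anti-aliased diagonals).  Components with area outside
    ``[min_area_px, max_area_px]`` are dropped.  Centroids are
    intensity-weighted (weight = darkness) when ``intensity`` is given,
    else uniform.
    """
    cfg = cfg or DetectConfig()
    binary = np.asarray(binary, dtype=bool)
    lbl = cc_label(binary, connectivity=2)
    weights = None
    if intensity is not None:
        weights = 255.0 - np.asarray(intensity, dtype=float)
    centroids, boxes, areas = [], [], []
    for region in regionprops(lbl, intensity_image=weights):
        if not (cfg.min_area_px <= region.area <= cfg.max_area_px):
            continue
        if weights is not None and region.centroid_weighted[0] == region.centroid_weighted[0]:
            cy, cx = region.centroid_weighted
        else:
            cy, cx = region.centroid
        minr, minc, maxr, maxc = region.bbox
        centroids.append((cx, cy))
        boxes.append(BoundingBox(int(minc), int(minr), int(maxc - minc), int(maxr - minr)))
        areas.append(float(region.area))
    if not centroids:
        return MarkerSet.empty()
    return MarkerSet(np.array(centroids, dtype=float), boxes, np.array(areas))


def detect_markers(img: np.ndarray, cfg: DetectConfig | None = None) -> MarkerSet:
    """Full detection pipeline.

    Order: enhance_contrast -> sharpen -> remove_border -> binarize ->
    extract_markers, then removal of markers clipped by the border (their
    centroids are biased).  Deterministic: identical input and config give
    an identical MarkerSet.
    """
    cfg = cfg or DetectConfig()
    img = _check_image(img)
    enhanced = enhance_contrast(img, cfg)
    sharp = sharpen(enhanced, cfg)
    cleaned = remove_border(sharp, cfg.border_margin_px)
    binary = binarize(cleaned)
    markers = extract_markers(binary, cfg, intensity=cleaned)
    if len(markers) == 0:
        return markers
    # drop markers clipped by the whitened border or the frame edge: a
    # partially visible circle has a biased centroid
    h, w = img.shape
    m = cfg.border_margin_px + 1
    keep = np.array(
        [b.x > m and b.y > m and b.x + b.w < w - m and b.y + b.h < h - m for b in markers.boxes]
    )
    return MarkerSet(
        centroids=markers.centroids[keep],
        boxes=[b for b, k in zip(markers.boxes, keep) if k],
        areas=markers.areas[keep],
    )
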