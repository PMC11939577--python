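"""Contour-based detection, classification and counting of A-lines and B-lines.

Starting from a segmentation output (probabilities or a binary mask), the
chain is: threshold at 0.5 -> small square dilation -> Gaussian blur + Canny
edge detection -> edge dilation -> connected external contours -> per-contour
bounding box -> geometric classification:

* A-line (horizontal reverberation) if  width  > 1.5 x height
* B-line (vertical comet tail)      if  height > 1.5 x width
* otherwise UNCLASSIFIED (reported, not counted)

If no contours survive, the original segmentation is retained, the fallback
flag is set and both counts are zero.

Canny thresholds are configured on the familiar 8-bit OpenCV scale (defaults
50/150); they are converted internally to scikit-image's normalized-gradient
scale (divide by 4 x 255, the unnormalized-Sobel full range for a binary
step).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, measure

__all__ = ["Label", "Detection", "LineReport", "PostprocessConfig",
           "binarize_and_dilate", "extract_contours", "classify_contour",
           "count_lines"]


class Label(str, enum.Enum):
    A_LINE = "A_LINE"
    B_LINE = "B_LINE"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class Detection:
    bbox: tuple[int, int, int, int]    # (x, y, w, h), 0-based top-left
    label: Label
    contour: np.ndarray                # (n, 2) boundary points, (row, col)
    area: int = 0

    def __post_init__(self) -> None:
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValueError(f"bounding box must have positive size, got {self.bbox}")


@dataclass
class LineReport:
    n_a_lines: int
    n_b_lines: int
    detections: list[Detection] = field(default_factory=list)
    fallback_used: bool = False


@dataclass
class PostprocessConfig:
    dilate_kernel: int = 3
    blur_sigma: float = 1.0
    canny_low: int = 50
    canny_high: int = 150
    edge_dilate_kernel: int = 3
    min_contour_area: int = 20

    def __post_init__(self) -> None:
        if self.canny_low >= self.canny_high:
            raise ValueError("canny_low must be smaller than canny_high")
        for name in ("dilate_kernel", "edge_dilate_kernel"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {v}")


def binarize_and_dilate(seg: np.ndarray,
                        cfg: PostprocessConfig | None = None) -> np.ndarray:
    """Threshold a probability map at 0.5 and dilate with a square kernel."""
    cfg = cfg or PostprocessConfig()
    arr = np.asarray(seg, dtype=np.float64)
    binary = arr > 0.5
    if not binary.any():
        return binary.astype(np.uint8)
    k = cfg.dilate_kernel
    out = ndimage.binary_dilation(binary, structure=np.ones((k, k), bool))
    return out.astype(np.uint8)


def _region_contour(region_mask: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Longest iso-contour of one region, in full-image (row, col) coords."""
    padded = np.pad(region_mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.argwhere(region_mask) + np.array(offset)
    longest = max(contours, key=len)
    return longest - 1.0 + np.array(offset, dtype=float)


def extract_contours(mask: np.ndarray,
                     cfg: PostprocessConfig | None = None) -> list[Detection]:
    """Blur + Canny + edge dilation, then external connected contours.

    Each surviving contour is returned as an unclassified :class:`Detection`
    with its bounding box and filled area; contours smaller than
    ``min_contour_area`` are discarded.
    """
    cfg = cfg or PostprocessConfig()
    m = np.asarray(mask) > 0.5
    if not m.any():
        return []
    # Regions touching the image border have no edge there, so their contour
    # never closes and fill_holes would split them; zero-padding restores a
    # closed outline, and the pad is cropped off after filling.
    pad = cfg.edge_dilate_kernel + 2
    mp = np.pad(m, pad)
    # Canny's internal Gaussian is the Algorithm's blur step; thresholds are
    # converted from the 8-bit unnormalized-Sobel convention.
    edges = feature.canny(mp.astype(np.float64), sigma=cfg.blur_sigma,
                          low_threshold=cfg.canny_low / 1020.0,
                          high_threshold=cfg.canny_high / 1020.0)
    k = cfg.edge_dilate_kernel
    edges = ndimage.binary_dilation(edges, structure=np.ones((k, k), bool))
    filled = ndimage.binary_fill_holes(edges)[pad:-pad, pad:-pad]
    labeled, _ = ndimage.label(filled, structure=np.ones((3, 3), int))
    detections: list[Detection] = []
    for region in measure.regionprops(labeled):
        if region.area < cfg.min_contour_area:
            continue
        y0, x0, y1, x1 = region.bbox
        contour = _region_contour(region.image, (y0, x0))
        detections.append(Detection(bbox=(x0, y0, x1 - x0, y1 - y0),
                                    label=Label.UNCLASSIFIED,
                                    contour=np.asarray(contour),
                                    area=int(region.area)))
    detections.sort(key=lambda d: (d.bbox[1], d.bbox[0]))
    return detections


def classify_contour(det: Detection) -> Label:
    """Aspect-ratio rule: wide boxes are A-lines, tall boxes are B-lines."""
    _, _, w, h = det.bbox
    if w > 1.5 * h:
        return Label.A_LINE
    if h > 1.5 * w:
        return Label.B_LINE
    return Label.UNCLASSIFIED


def _draw_box(canvas: np.ndarray, bbox: tuple[int, int, int, int],
              color: tuple[int, int, int]) -> None:
    x, y, w, h = bbox
    y1, x1 = min(y + h, canvas.shape[0]) - 1, min(x + w, canvas.shape[1]) - 1
    canvas[y, x:x1 + 1] = color
    canvas[y1, x:x1 + 1] = color
    canvas[y:y1 + 1, x] = color
    canvas[y:y1 + 1, x1] = color


def count_lines(seg: np.ndarray, cfg: PostprocessConfig | None = None
                ) -> tuple[LineReport, np.ndarray]:
    """Full post-processing chain; returns the report and an RGB overlay.

    A-line boxes are drawn yellow, B-line boxes red, unclassified boxes gray.
    With no detected contours the original segmentation is retained as the
    overlay and ``fallback_used`` is set.
    """
    cfg = cfg or PostprocessConfig()
    arr = np.asarray(seg, dtype=np.float64)
    base = np.clip(arr, 0.0, 1.0)
    overlay = (np.stack([base] * 3, axis=-1) * 255).astype(np.uint8)
    mask = binarize_and_dilate(arr, cfg)
    detections = extract_contours(mask, cfg)
    if not detections:
        return LineReport(0, 0, [], fallback_used=True), overlay
    colors = {Label.A_LINE: (255, 220, 0), Label.B_LINE: (255, 40, 40),
              Label.UNCLASSIFIED: (160, 160, 160)}
    n_a = n_b = 0
    for det in detections:
        det.label = classify_contour(det)
        n_a += det.label is Label.A_LINE
        n_b += det.label is Label.B_LINE
        _draw_box(overlay, det.bbox, colors[det.label])
    return LineReport(n_a, n_b, detections, fallback_used=False), overlay
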