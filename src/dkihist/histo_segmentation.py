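"""Positive-pixel color segmentation of H&E-like histology images.

Pixels inside a region of interest (ROI) are partitioned into three tissue
classes by a hue/saturation/value rule modeled on the positive-pixel-count
family of digital-pathology algorithms:

* **background / luminal space** — unstained: saturation below
  ``saturation_min`` or brightness at/above ``white_value_min``;
* **positive / cellularity** — stained, with circular hue distance to
  ``hue_center`` at most ``hue_window / 2`` (hematoxylin blue-purple sits
  near hue 0.7 on the [0, 1) hue circle);
* **negative / fibromuscular stromal matrix (FSM)** — any other stained
  pixel (eosin pink).

Fractional areas are simple pixel-count ratios over the ROI, so
cellularity + FSM + luminal = 1 exactly; luminal space is the complement of
the two stained classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from skimage.color import rgb2hsv
from skimage.util import img_as_float

__all__ = [
    "SegmentationSettings",
    "PixelClassMap",
    "TissueFractions",
    "LABEL_BACKGROUND",
    "LABEL_POSITIVE",
    "LABEL_NEGATIVE",
    "LABEL_OUTSIDE",
    "circular_hue_distance",
    "classify_pixels",
    "compute_tissue_fractions",
    "rasterize_roi",
]

LABEL_BACKGROUND = 0  # luminal space
LABEL_POSITIVE = 1  # cellularity
LABEL_NEGATIVE = 2  # fibromuscular stromal matrix
LABEL_OUTSIDE = 255  # not in ROI


@dataclass(frozen=True)
class SegmentationSettings:
    """Hue-window classification thresholds (hue axis normalized to [0, 1))."""

    hue_center: float = 0.70
    hue_window: float = 0.35
    saturation_min: float = 0.05
    white_value_min: float = 0.94

    def __post_init__(self) -> None:
        if not 0.0 <= self.hue_center < 1.0:
            raise ValueError("hue_center must be in [0, 1)")
        if not 0.0 < self.hue_window < 1.0:
            raise ValueError("hue_window must be in (0, 1)")
        if not 0.0 <= self.saturation_min < 1.0:
            raise ValueError("saturation_min must be in [0, 1)")
        if not 0.0 < self.white_value_min <= 1.0:
            raise ValueError("white_value_min must be in (0, 1]")


@dataclass
class PixelClassMap:
    """Per-pixel class labels inside an ROI (outside pixels = 255)."""

    labels: np.ndarray
    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.labels.shape != self.roi_mask.shape:
            raise ValueError("labels and roi_mask must share shape")

    def count(self, label: int) -> int:
        return int(np.sum(self.labels[self.roi_mask] == label))


@dataclass(frozen=True)
class TissueFractions:
    """Fractional areas of the three tissue classes, summing to 1."""

    cellularity: float
    fsm: float
    luminal: float

    def __post_init__(self) -> None:
        for name in ("cellularity", "fsm", "luminal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = self.cellularity + self.fsm + self.luminal
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")

    @classmethod
    def from_weights(cls, cellularity: float, fsm: float, luminal: float):
        """Normalize non-negative weights (e.g. published medians that sum
        to slightly less than 1) into a valid composition."""
        w = np.asarray([cellularity, fsm, luminal], dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
        return cls(cellularity=float(w[0]), fsm=float(w[1]), luminal=float(w[2]))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.cellularity, self.fsm, self.luminal)


def circular_hue_distance(h1, h2):
    """Distance on the unit hue circle: min(|h1-h2|, 1-|h1-h2|)."""
    d = np.abs(np.asarray(h1, dtype=float) - np.asarray(h2, dtype=float)) % 1.0
    return np.minimum(d, 1.0 - d)


def classify_pixels(
    image: np.ndarray,
    roi_mask: np.ndarray,
    settings: SegmentationSettings | None = None,
) -> PixelClassMap:
    """Label every ROI pixel as positive, negative or background.

    ``image`` is an RGB array (uint8 or float in [0, 1]); ``roi_mask`` a
    boolean array of the same spatial shape with at least one True pixel.
    The three labels partition the ROI exactly.
    """
    settings = settings or SegmentationSettings()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {image.shape}")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != image.shape[:2]:
        raise ValueError("roi_mask shape must match image spatial shape")
    if not roi_mask.any():
        raise ValueError("ROI is empty")

    hsv = rgb2hsv(img_as_float(image))
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    background = (sat < settings.saturation_min) | (val >= settings.white_value_min)
    in_window = (
        circular_hue_distance(hue, settings.hue_center) <= settings.hue_window / 2.0
    )

    labels = np.full(image.shape[:2], LABEL_OUTSIDE, dtype=np.uint8)
    labels[roi_mask] = LABEL_NEGATIVE
    labels[roi_mask & background] = LABEL_BACKGROUND
    labels[roi_mask & ~background & in_window] = LABEL_POSITIVE
    return PixelClassMap(labels=labels, roi_mask=roi_mask)


def compute_tissue_fractions(classes: PixelClassMap) -> TissueFractions:
    """Pixel-count ratios of the three classes over the ROI."""
    n_roi = int(classes.roi_mask.sum())
    if n_roi == 0:
        raise ValueError("ROI is empty")
    n_pos = classes.count(LABEL_POSITIVE)
    n_neg = classes.count(LABEL_NEGATIVE)
    # luminal space is the ROI remainder after the two stained classes
    return TissueFractions(
        cellularity=n_pos / n_roi,
        fsm=n_neg / n_roi,
        luminal=(n_roi - n_pos - n_neg) / n_roi,
    )


def rasterize_roi(polygon, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon (vertices in (x, y) pixel coordinates) to a mask.

    A pixel at (row, col) is included iff its center (col + 0.5, row + 0.5)
    lies strictly inside the polygon (even-odd rule for simple polygons);
    coordinates are 0-based.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    poly = shapely.Polygon(verts)
    if not poly.is_valid:
        raise ValueError("polygon must be non-self-intersecting")
    if poly.area == 0.0:
        raise ValueError("degenerate polygon with zero area")
    h, w = int(shape[0]), int(shape[1])
    xs, ys = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    mask = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(h, w)
    if not mask.any():
        raise ValueError("polygon contains no pixel centers within the image")
    return mask
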