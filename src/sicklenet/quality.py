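"""Image-quality scoring and top-N selection.

Two cheap quality proxies are computed per image: mean HSV brightness
(the V channel, i.e. the per-pixel max over R, G, B) and a zoom-level proxy
(the area enclosed by the largest external contour of the binarized image).
Both are min-max normalized within the batch being filtered, combined as a
weighted sum, and the top-N images per class are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2gray
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .synthetic import LabeledDataset, SmearImage

logger = logging.getLogger(__name__)

# Blurred-grayscale dynamic range (on [0,1]) below which an image is treated
# as contour-free: Otsu on a near-uniform background (noise plus a shallow
# illumination gradient) would otherwise bisect it and report a spurious
# half-canvas "contour".  Stained cells sit ~0.3 below the background, so
# genuine cell-bearing images clear this floor comfortably.
_CONTRAST_FLOOR = 0.15

MANIFEST_COLUMNS = [
    "image_id",
    "label",
    "brightness_raw",
    "zoom_raw",
    "brightness_norm",
    "zoom_norm",
    "combined",
    "selected",
]


@dataclass
class FilterConfig:
    """Weights and knobs for the quality filter.

    The combination weights ``w_b`` (brightness) and ``w_z`` (zoom) must be
    non-negative and sum to 1; equal weights are the default.
    """

    w_b: float = 0.5
    w_z: float = 0.5
    n_train_per_class: int = 350
    n_test_per_class: int = 100
    blur_kernel: int = 5
    threshold_mode: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 128.0

    def __post_init__(self) -> None:
        if self.w_b < 0 or self.w_z < 0 or abs(self.w_b + self.w_z - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if self.blur_kernel < 1 or self.blur_kernel % 2 == 0:
            raise ValueError("blur_kernel must be odd and >= 1")
        if self.n_train_per_class < 0 or self.n_test_per_class < 0:
            raise ValueError("selection counts must be non-negative")
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


@dataclass
class QualityRecord:
    image_id: str
    label: str
    brightness_raw: float
    zoom_raw: float
    brightness_norm: float = np.nan
    zoom_norm: float = np.nan
    combined: float = np.nan
    selected: bool = False


def _pixels(image) -> np.ndarray:
    px = image.pixels if isinstance(image, SmearImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if px.size == 0:
        raise ValueError("empty image")
    return px


def brightness_score(image) -> float:
    """Mean of the HSV value channel: V(pixel) = max(R, G, B), range 0-255."""
    px = _pixels(image).astype(float)
    return float(px.max(axis=2).mean())


def zoom_score(image, config: FilterConfig | None = None) -> float:
    """Area enclosed by the largest external contour, in pixels squared.

    Pipeline: grayscale -> Gaussian blur -> binarization (Otsu by default)
    -> connected foreground regions -> filled area of the largest region.
    Returns 0 for blank / contour-free images.
    """
    config = config or FilterConfig()
    px = _pixels(image)
    gray = rgb2gray(px)  # [0, 1]
    # sigma matching an OpenCV-style k x k Gaussian kernel
    k = config.blur_kernel
    sigma = 0.3 * ((k - 1) * 0.5 - 1) + 0.8 if k > 1 else 0.0
    blurred = gaussian(gray, sigma=sigma, preserve_range=True) if sigma > 0 else gray

    if blurred.max() - blurred.min() < _CONTRAST_FLOOR:
        return 0.0
    if config.threshold_mode == "otsu":
        thresh = threshold_otsu(blurred)
    else:
        thresh = config.fixed_threshold / 255.0
    # Cells are darker than the stained background: foreground = below threshold.
    binary = blurred < thresh
    labelled = cc_label(binary)
    if labelled.max() == 0:
        return 0.0
    return float(max(r.area_filled for r in regionprops(labelled)))


def minmax_normalize(values: Sequence[float]) -> List[float]:
    """Linear rescale to [0, 1]; a constant batch maps to all zeros."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty list")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return [0.0] * arr.size
    return list((arr - lo) / (hi - lo))


def score_batch(
    images: Sequence, image_ids: Sequence[str], labels: Sequence[str],
    config: FilterConfig | None = None,
) -> List[QualityRecord]:
    """Score a batch and normalize within it (batch-local min-max)."""
    config = config or FilterConfig()
    records = [
        QualityRecord(
            image_id=iid,
            label=lbl,
            brightness_raw=brightness_score(im),
            zoom_raw=zoom_score(im, config),
        )
        for im, iid, lbl in zip(images, image_ids, labels)
    ]
    b_norm = minmax_normalize([r.brightness_raw for r in records])
    z_norm = minmax_normalize([r.zoom_raw for r in records])
    for r, bn, zn in zip(records, b_norm, z_norm):
        r.brightness_norm = bn
        r.zoom_norm = zn
        r.combined = config.w_b * bn + config.w_z * zn
    return records


def score_dataset(dataset: LabeledDataset, config: FilterConfig | None = None,
                  id_prefix: str = "img") -> List[QualityRecord]:
    ids = [f"{id_prefix}_{i:05d}" for i in range(len(dataset))]
    labels = [im.label for im in dataset]
    return score_batch(list(dataset), ids, labels, config)


def rank_and_select(
    records: List[QualityRecord], n_per_class: int, config: FilterConfig | None = None
) -> List[QualityRecord]:
    """Retain the top-``n_per_class`` records per class by combined score.

    Ties are broken by ``image_id`` ascending.  A class with fewer records
    than requested is retained whole (with a warning).  Marks ``selected``
    in place and returns the selected records in rank order.
    """
    if n_per_class < 0:
        raise ValueError("n_per_class must be non-negative")
    for r in records:
        r.selected = False
    selected: List[QualityRecord] = []
    for cls in sorted({r.label for r in records}):
        cls_records = [r for r in records if r.label == cls]
        cls_records.sort(key=lambda r: (-r.combined, r.image_id))
        if len(cls_records) < n_per_class:
            logger.warning(
                "class %r has %d records, fewer than requested %d; keeping all",
                cls, len(cls_records), n_per_class,
            )
        keep = cls_records[:n_per_class]
        for r in keep:
            r.selected = True
        selected.extend(keep)
    return selected


def records_to_frame(records: Sequence[QualityRecord]) -> pd.DataFrame:
    rows = [
        {
            "image_id": r.image_id,
            "label": r.label,
            "brightness_raw": r.brightness_raw,
            "zoom_raw": r.zoom_raw,
            "brightness_norm": r.brightness_norm,
            "zoom_norm": r.zoom_norm,
            "combined": r.combined,
            "selected": r.selected,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def filter_dataset(
    dataset: LabeledDataset, n_per_class: int, config: FilterConfig | None = None,
    id_prefix: str = "img",
) -> tuple[LabeledDataset, pd.DataFrame]:
    """Score, rank and select; returns (filtered dataset, full record frame)."""
    records = score_dataset(dataset, config, id_prefix=id_prefix)
    rank_and_select(records, n_per_class, config)
    id_to_index = {f"{id_prefix}_{i:05d}": i for i in range(len(dataset))}
    kept = [dataset[id_to_index[r.image_id]] for r in records if r.selected]
    return LabeledDataset(images=kept), records_to_frame(records)
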