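"""Tumor-area derivation, overlap metrics, invasive margin, composition.

The primary tumor region is derived from the class map by a morphological
recipe: binarize the tumor-cell, necrosis, and mucus classes; close the
tumor-cell map; merge every necrosis/mucus connected component that
touches a tumor component (pathologically, necrotic and mucinous areas
embedded in or abutting the tumor belong to it); close-then-open the
union to regularize the outline; and finally fill the holes of each
component so the mask is the area enclosed by each outer contour.
Overlap with an annotated reference is scored by IoU and Dice.

The invasive margin is the band straddling the tumor boundary: the tumor
mask is dilated by the margin width, intersected with non-tumor tissue,
and the intersection dilated once more (same width) and re-clipped to
tissue, extending the band into both the tumor and the healthy side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fusion import ClassMap
from .slide_model import ForegroundMask

__all__ = [
    "TumorAreaResult",
    "OverlapMetrics",
    "CompositionResult",
    "TUMOR_MERGE_CLASSES",
    "tumor_area",
    "overlap",
    "invasive_margin",
    "composition",
]

#: Class names merged into the tumor region (order: primary, then merged-in).
TUMOR_MERGE_CLASSES = ("tumor cells", "necrosis", "mucus")

DEFAULT_CLOSING_RADIUS = 10   # px at analysis resolution (~35 um)
DEFAULT_OPENING_RADIUS = 5
DEFAULT_MARGIN_WIDTH_UM = 500.0


@dataclass
class TumorAreaResult:
    mask: np.ndarray
    area_mm2: float
    components: int


@dataclass
class OverlapMetrics:
    iou: float
    dice: float
    tp: int
    fp: int
    fn: int


@dataclass
class CompositionResult:
    """Class-pixel ratios inside a reference tumor region."""

    ratios: dict
    region_pixels: int


def _dilate_disk(mask: np.ndarray, radius: float) -> np.ndarray:
    """Dilation by an exact Euclidean disk, via the distance transform of
    the complement (memory-light even for large radii)."""
    if radius <= 0 or not mask.any():
        return mask.copy()
    return ndimage.distance_transform_edt(~mask) <= radius


def _erode_disk(mask: np.ndarray, radius: float) -> np.ndarray:
    # duality: erosion = complement of the dilated complement; the
    # structuring element is clipped at the image edge (borders are not
    # eaten by erosion)
    return ~_dilate_disk(~mask, radius)


def _close_disk(mask: np.ndarray, radius: float) -> np.ndarray:
    return _erode_disk(_dilate_disk(mask, radius), radius)


def _open_disk(mask: np.ndarray, radius: float) -> np.ndarray:
    return _dilate_disk(_erode_disk(mask, radius), radius)


def _class_mask(class_map: ClassMap, name: str) -> np.ndarray:
    if name not in class_map.class_names:
        raise ValueError(f"class {name!r} not in class map legend {class_map.class_names}")
    return class_map.raster == class_map.code(name)


def tumor_area(
    class_map: ClassMap,
    closing_radius: int = DEFAULT_CLOSING_RADIUS,
    opening_radius: int = DEFAULT_OPENING_RADIUS,
    classes: tuple[str, str, str] = TUMOR_MERGE_CLASSES,
) -> TumorAreaResult:
    """Derive the primary tumor mask and its area in mm^2.

    Steps: close the tumor-cell map; add necrosis/mucus components in
    8-connected contact with it (contact tested after a 1 px dilation);
    close then open the union with disk elements; fill each component's
    holes.  Radii are in analysis-plane pixels.
    """
    tumor_name, necrosis_name, mucus_name = classes
    tumor = _class_mask(class_map, tumor_name)
    nm = _class_mask(class_map, necrosis_name) | _class_mask(class_map, mucus_name)

    if closing_radius > 0:
        tumor = _close_disk(tumor, closing_radius)

    # keep only necrosis/mucus components adjacent to a tumor component
    eight = np.ones((3, 3), dtype=bool)
    contact_zone = ndimage.binary_dilation(tumor, structure=eight)
    nm_labels, n_nm = ndimage.label(nm, structure=eight)
    if n_nm:
        touching = np.unique(nm_labels[contact_zone & (nm_labels > 0)])
        keep = np.zeros(n_nm + 1, dtype=bool)
        keep[touching] = True
        nm = keep[nm_labels]
    union = tumor | nm

    if closing_radius > 0:
        union = _close_disk(union, closing_radius)
    if opening_radius > 0:
        union = _open_disk(union, opening_radius)

    # outer-contour rule: fill holes of every connected component
    mask = ndimage.binary_fill_holes(union)
    _, components = ndimage.label(mask, structure=eight)
    px_mm = class_map.mpp / 1000.0
    return TumorAreaResult(
        mask=mask,
        area_mm2=round(float(mask.sum()) * px_mm * px_mm, 3),
        components=int(components),
    )


def overlap(est: np.ndarray, gt: np.ndarray) -> OverlapMetrics:
    """IoU = TP/(TP+FP+FN) and Dice = 2TP/(2TP+FP+FN) of two binary masks."""
    est = np.asarray(est, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if est.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {est.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(est & gt))
    fp = int(np.count_nonzero(est & ~gt))
    fn = int(np.count_nonzero(~est & gt))
    denom = tp + fp + fn
    iou = tp / denom if denom else 1.0
    dice = 2 * tp / (2 * tp + fp + fn) if denom else 1.0
    return OverlapMetrics(iou=iou, dice=dice, tp=tp, fp=fp, fn=fn)


def invasive_margin(
    tumor: np.ndarray,
    tissue: ForegroundMask,
    width_um: float = DEFAULT_MARGIN_WIDTH_UM,
    mpp: float = 3.54,
) -> np.ndarray:
    """Invasive-margin band of half-width ``width_um`` around the tumor
    boundary, restricted to tissue and reaching into both sides."""
    if width_um <= 0:
        raise ValueError("margin width must be positive")
    tumor = np.asarray(tumor, dtype=bool)
    tissue_mask = tissue.mask
    if tumor.shape != tissue_mask.shape:
        raise ValueError("tumor and tissue masks not aligned")
    if not tissue_mask.any():
        return np.zeros_like(tumor)
    w = max(1, int(round(width_um / mpp)))
    outside_band = _dilate_disk(tumor, w) & tissue_mask & ~tumor
    band = _dilate_disk(outside_band, w) & tissue_mask
    return band


def composition(class_map: ClassMap, reference_region: np.ndarray, classes=TUMOR_MERGE_CLASSES) -> CompositionResult:
    """Per-class pixel ratios within a reference (e.g. annotated tumor)
    region; all ratios share the region pixel count as denominator."""
    region = np.asarray(reference_region, dtype=bool)
    if region.shape != class_map.raster.shape:
        raise ValueError("reference region not aligned with class map")
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty reference region")
    inside = class_map.raster[region]
    ratios = {name: float(np.count_nonzero(inside == class_map.code(name)) / n) for name in classes}
    return CompositionResult(ratios=ratios, region_pixels=n)
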