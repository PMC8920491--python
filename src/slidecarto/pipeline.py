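"""End-to-end cartography: slide -> superpixels -> patches -> class map.

``run_cartography`` wires the stages together: select the analysis plane,
detect tissue and crop to its bounding box, deconvolve the stains,
cluster superpixels in [H, E, x, y], tile the native bounding box into
patches, assign and subsample patches per superpixel, classify them with
the supplied patch-probability classifier (streaming per superpixel, so
the full native raster is never resident), fuse patch outputs, apply
rejection, and render the class map at analysis resolution.

``run_endpoints`` evaluates a class map against ground truth and derives
the tumor mask, overlap metrics, invasive margin, and composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import evaluation, fusion, patching, superpixels, tumor_endpoints
from .config import PipelineConfig
from .fusion import ClassMap, SuperpixelLabeling
from .slide_model import ForegroundMask, SlidePyramid, foreground_mask, tissue_bounding_box
from .stain import deconvolve, rgb_to_od
from .superpixels import SuperpixelMap

logger = logging.getLogger(__name__)

__all__ = ["CartographyResult", "EndpointReport", "run_cartography", "run_endpoints"]


@dataclass
class CartographyResult:
    """Everything a cartography run produces (rasters at analysis scale)."""

    class_map: ClassMap                    # full analysis plane
    labeling: SuperpixelLabeling
    spmap: SuperpixelMap                   # cropped to the tissue bbox
    tissue: ForegroundMask                 # full analysis plane
    bbox: tuple[int, int, int, int]        # analysis-plane coords
    manifest: dict


@dataclass
class EndpointReport:
    metrics: evaluation.MetricsReport | None
    confusion: evaluation.ConfusionMatrix | None
    tumor: tumor_endpoints.TumorAreaResult
    overlap: tumor_endpoints.OverlapMetrics | None
    margin: np.ndarray
    composition: tumor_endpoints.CompositionResult | None


def run_cartography(
    pyramid: SlidePyramid,
    classifier,
    config: PipelineConfig,
    batch_size: int = 64,
) -> CartographyResult:
    """Run the full superpixel-cartography pipeline on one slide."""
    ds = config.analysis_downsample
    plane = pyramid.select_plane(ds)
    logger.info("analysis plane %sx%s at %.2f um/px", *plane.shape, plane.mpp)

    tissue = foreground_mask(plane, config.white_threshold)
    bbox = tissue_bounding_box(tissue)
    r0, c0, r1, c1 = bbox
    crop = plane.pixels[r0:r1, c0:c1]
    logger.info("tissue bbox %s (%d px)", bbox, crop.shape[0] * crop.shape[1])

    matrix = config.resolve_stain_matrix()
    channels = deconvolve(rgb_to_od(crop), matrix)

    k = superpixels.compute_k(crop.shape[0] * crop.shape[1], config.superpixels.avg_size_px)
    spmap = superpixels.slic_he(
        _cropped_plane(plane, crop), channels, config.superpixels, k
    )
    fg_crop = ForegroundMask(mask=tissue.mask[r0:r1, c0:c1], white_threshold=tissue.white_threshold)
    spmap = superpixels.mark_background(spmap, fg_crop, config.superpixels.background_fraction)
    logger.info("%d superpixels (%d background)", len(spmap.ids), len(spmap.background_ids))

    native_bbox = (r0 * ds, c0 * ds, r1 * ds, c1 * ds)
    grid = patching.build_grid(native_bbox, config.patch_size)
    assignment = patching.assign_patches(grid, spmap, config.coverage_threshold, ds)
    sample = patching.sample_patches(assignment, config.patch_limit, config.seed)
    logger.info(
        "patches: %d in grid, %d assigned, %d selected",
        grid.n_patches, assignment.n_assigned, sample.n_selected,
    )

    probs_by_superpixel = {}
    for sp_id in sorted(sample.selected):
        coords = sample.selected[sp_id]
        probs = []
        for start in range(0, len(coords), batch_size):
            batch = np.stack(
                [
                    pyramid.read_region(*grid.patch_origin(i, j), config.patch_size, config.patch_size)
                    for i, j in coords[start : start + batch_size]
                ]
            )
            probs.append(fusion.classify_patches(classifier, batch, len(config.class_names)))
        probs_by_superpixel[sp_id] = np.concatenate(probs)

    labeling = fusion.build_labeling(spmap, probs_by_superpixel, config.class_names)
    labeling = fusion.apply_rejection(labeling, config.rejection_threshold)

    cropped_map = fusion.render_class_map(spmap, labeling, plane.mpp)
    raster = np.full(plane.shape, fusion.BACKGROUND, dtype=np.uint8)
    raster[r0:r1, c0:c1] = cropped_map.raster
    class_map = ClassMap(raster=raster, class_names=cropped_map.class_names, mpp=plane.mpp)

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "bbox_analysis": list(bbox),
        "n_superpixels": len(spmap.ids),
        "n_background_superpixels": len(spmap.background_ids),
        "n_rejected_superpixels": len(labeling.ids_with_status(fusion.Status.REJECTED)),
        "n_unclassified_superpixels": len(labeling.ids_with_status(fusion.Status.UNCLASSIFIED)),
        "n_patches_grid": grid.n_patches,
        "n_patches_assigned": assignment.n_assigned,
        "n_patches_classified": sample.n_selected,
    }
    return CartographyResult(
        class_map=class_map, labeling=labeling, spmap=spmap, tissue=tissue, bbox=bbox, manifest=manifest
    )


def _cropped_plane(plane, crop):
    from .slide_model import SlidePlane

    return SlidePlane(pixels=crop, mpp=plane.mpp, downsample=plane.downsample)


def run_endpoints(
    class_map: ClassMap,
    config: PipelineConfig,
    tissue: ForegroundMask,
    gt: np.ndarray | None = None,
    gt_tumor_mask: np.ndarray | None = None,
) -> EndpointReport:
    """Evaluate a class map (if ground truth is given) and derive tumor
    area, overlap, invasive margin, and composition.

    ``gt`` is a class-code raster (0 = unannotated).  ``gt_tumor_mask``
    optionally supplies the annotated tumor region; when absent but ``gt``
    is present, it is derived from ``gt`` by the same morphological rules.
    """
    metrics_report = None
    cm = None
    if gt is not None:
        cm = evaluation.confusion(gt, class_map)
        rejected = int(np.count_nonzero(class_map.raster == fusion.REJECTED))
        denom = rejected + cm.total
        metrics_report = evaluation.metrics(cm, rejected_fraction=rejected / denom if denom else 0.0)
    else:
        logger.warning("no ground truth given: skipping pixelwise evaluation")

    tumor = tumor_endpoints.tumor_area(class_map, config.closing_radius, config.opening_radius)
    ov = None
    comp = None
    if gt_tumor_mask is None and gt is not None:
        gt_map = ClassMap(raster=gt, class_names=class_map.class_names, mpp=class_map.mpp)
        gt_tumor_mask = tumor_endpoints.tumor_area(gt_map, config.closing_radius, config.opening_radius).mask
    if gt_tumor_mask is not None:
        ov = tumor_endpoints.overlap(tumor.mask, gt_tumor_mask)
        if gt_tumor_mask.any():
            comp = tumor_endpoints.composition(class_map, gt_tumor_mask)
    margin = tumor_endpoints.invasive_margin(tumor.mask, tissue, config.margin_width_um, class_map.mpp)
    return EndpointReport(
        metrics=metrics_report, confusion=cm, tumor=tumor, overlap=ov, margin=margin, composition=comp
    )
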