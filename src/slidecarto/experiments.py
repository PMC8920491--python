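"""Reference experiments on synthetic phantoms.

Each function reruns the full pipeline under fixed study conditions and
returns measured quantities; nothing here is precomputed.  Problem sizes
are desk-scale phantoms (native rasters of a few hundred megapixels down
to tens of megapixels) chosen so each experiment completes in minutes on
one CPU while exercising every stage at the real resolution ratios.

Conditions:

* ``recovery_experiment`` - noise-free oracle, Voronoi regions with a
  linear scale 3x the superpixel scale (180 px vs. 60 px), so errors are
  confined to region boundaries.
* ``rejection_experiment`` - symmetric patch-label noise epsilon = 0.2,
  20 seeds, rejection threshold 0.1, mirroring the before/after rejection
  comparison.
* ``patch_budget_experiment`` - noise-free oracle on phantoms whose
  superpixels average ~20 assigned patches each (the default 3600 px
  superpixel size yields this, since the 50% coverage rule lets a
  superpixel own more patch blocks than its area alone implies),
  comparing a 10-patch limit against unrestricted classification.
* ``tumor_phantom_experiment`` - a structured phantom with a tumor disk,
  enclosed necrosis, an abutting mucus lobe, and a distant necrosis
  island; scores the derived tumor mask against the ground-truth-derived
  one by IoU/Dice and reports composition ratios.
"""

from __future__ import annotations

import numpy as np

from . import evaluation, fusion, tumor_endpoints
from .config import PipelineConfig
from .fusion import ClassMap
from .pipeline import run_cartography, run_endpoints
from .slide_model import SlidePyramid
from .synthetic import OracleNoise, Phantom, PhantomSpec, make_phantom, oracle_classifier, render_native_rgb, default_classes

__all__ = [
    "run_phantom",
    "recovery_experiment",
    "rejection_experiment",
    "patch_budget_experiment",
    "tumor_phantom_experiment",
]

NATIVE_MPP = 0.22


def _embed(cropped: np.ndarray, shape: tuple[int, int], bbox) -> np.ndarray:
    out = np.full(shape, fusion.BACKGROUND, dtype=np.uint8)
    r0, c0, r1, c1 = bbox
    out[r0:r1, c0:c1] = cropped
    return out


def run_phantom(phantom: Phantom, classifier, config: PipelineConfig):
    """Run cartography on an in-memory phantom; returns the result plus the
    pixel accuracy over jointly labeled pixels."""
    pyramid = SlidePyramid.from_array(phantom.native_rgb, NATIVE_MPP)
    result = run_cartography(pyramid, classifier, config)
    cm = evaluation.confusion(phantom.gt_labels, result.class_map)
    accuracy = evaluation.metrics(cm).accuracy if cm.total else float("nan")
    return result, accuracy


def recovery_experiment(n_seeds: int = 5, base_seed: int = 0) -> dict:
    """End-to-end recovery with a noise-free oracle and regions 3x the
    superpixel scale; returns per-seed and mean pixel accuracy."""
    accuracies = []
    for s in range(n_seeds):
        spec = PhantomSpec(analysis_shape=(448, 448), region_scale_px=180, seed=base_seed + s)
        phantom = make_phantom(spec)
        clf = oracle_classifier(spec, seed=base_seed + s)
        config = PipelineConfig(seed=base_seed + s, class_names=spec.class_names)
        _, acc = run_phantom(phantom, clf, config)
        accuracies.append(acc)
    return {"accuracies": accuracies, "mean_accuracy": float(np.mean(accuracies)), "n_seeds": n_seeds}


def rejection_experiment(
    n_seeds: int = 20,
    epsilon: float = 0.2,
    threshold: float = 0.1,
    base_seed: int = 0,
) -> dict:
    """Before/after comparison of confidence-based rejection under
    symmetric patch noise.  Accumulates correct/false pixel counts over
    seeds and reports accuracies, the rejected fraction, and the relative
    drop of true and false predictions."""
    acc_before, acc_after = [], []
    correct_before = false_before = correct_after = false_after = 0
    n_before_total = n_after_total = 0
    for s in range(n_seeds):
        seed = base_seed + s
        spec = PhantomSpec(analysis_shape=(320, 320), region_scale_px=96, seed=seed)
        phantom = make_phantom(spec)
        clf = oracle_classifier(spec, noise=OracleNoise(mode="symmetric", epsilon=epsilon), seed=seed)
        config = PipelineConfig(seed=seed, class_names=spec.class_names, rejection_threshold=0.0)
        result, _ = run_phantom(phantom, clf, config)

        before = result.class_map
        rejected = fusion.apply_rejection(result.labeling, threshold)
        after_crop = fusion.render_class_map(result.spmap, rejected, before.mpp)
        after = ClassMap(
            raster=_embed(after_crop.raster, before.raster.shape, result.bbox),
            class_names=before.class_names,
            mpp=before.mpp,
        )
        report = evaluation.rejection_report(phantom.gt_labels, before, after)
        acc_before.append(report["accuracy_before"])
        acc_after.append(report["accuracy_after"])
        correct_before += report["correct_before"]
        false_before += report["false_before"]
        correct_after += report["correct_after"]
        false_after += report["false_after"]
        n_before_total += report["correct_before"] + report["false_before"]
        n_after_total += report["correct_after"] + report["false_after"]
    return {
        "mean_accuracy_before": float(np.mean(acc_before)),
        "mean_accuracy_after": float(np.mean(acc_after)),
        "true_drop_fraction": (correct_before - correct_after) / correct_before,
        "false_drop_fraction": (false_before - false_after) / false_before,
        "rejected_pixel_fraction": (n_before_total - n_after_total) / n_before_total,
        "n_seeds": n_seeds,
        "epsilon": epsilon,
        "threshold": threshold,
    }


def patch_budget_experiment(seed: int = 0, limit: int = 10) -> dict:
    """Patch-limit economy: classified-patch count and accuracy with the
    default 10-patch limit vs. unrestricted classification, noise-free."""
    spec = PhantomSpec(analysis_shape=(384, 384), region_scale_px=120, seed=seed)
    phantom = make_phantom(spec)

    results = {}
    for name, lim in (("limited", limit), ("unrestricted", 10**9)):
        clf = oracle_classifier(spec, seed=seed)
        config = PipelineConfig(seed=seed, class_names=spec.class_names, patch_limit=lim)
        result, acc = run_phantom(phantom, clf, config)
        results[name] = (result.manifest, acc)

    manifest_lim, acc_lim = results["limited"]
    manifest_full, acc_full = results["unrestricted"]
    mean_assigned = manifest_full["n_patches_assigned"] / max(
        1, manifest_full["n_superpixels"] - manifest_full["n_background_superpixels"]
        - manifest_full["n_unclassified_superpixels"]
    )
    return {
        "classified_limited": manifest_lim["n_patches_classified"],
        "classified_unrestricted": manifest_full["n_patches_classified"],
        "classified_fraction": manifest_lim["n_patches_classified"]
        / manifest_full["n_patches_classified"],
        "accuracy_limited": acc_lim,
        "accuracy_unrestricted": acc_full,
        "accuracy_drop": acc_full - acc_lim,
        "mean_assigned_per_superpixel": mean_assigned,
    }


def _tumor_labels(shape=(256, 256), margin=8) -> np.ndarray:
    """Structured label map: mucosa/muscle background halves, a tumor disk
    with an enclosed necrotic core, an abutting mucus lobe, and a distant
    necrosis island."""
    classes = {name: i + 1 for i, name in enumerate(c.name for c in default_classes())}
    h, w = shape
    labels = np.full(shape, classes["mucosa"], dtype=np.uint8)
    labels[:, w // 2 :] = classes["muscle"]
    rr, cc = np.mgrid[0:h, 0:w]

    cy, cx, r_tumor = h // 2, w // 2, 60
    d2 = (rr - cy) ** 2 + (cc - cx) ** 2
    labels[d2 <= r_tumor**2] = classes["tumor cells"]
    labels[d2 <= 18**2] = classes["necrosis"]                       # enclosed core
    d2_mucus = (rr - cy) ** 2 + (cc - (cx + r_tumor + 10)) ** 2
    labels[d2_mucus <= 16**2] = classes["mucus"]                    # abutting lobe
    d2_far = (rr - (margin + 22)) ** 2 + (cc - (margin + 22)) ** 2
    labels[d2_far <= 10**2] = classes["necrosis"]                   # distant island

    labels[:margin, :] = 0
    labels[-margin:, :] = 0
    labels[:, :margin] = 0
    labels[:, -margin:] = 0
    return labels


def tumor_phantom_experiment(seed: int = 0) -> dict:
    """Tumor endpoints on a structured phantom: runs the noise-free
    pipeline, derives the tumor mask from prediction and ground truth with
    identical rules, and reports IoU, Dice, areas, and composition."""
    spec = PhantomSpec(analysis_shape=(256, 256), seed=seed, n_fissures=0)
    labels = _tumor_labels(spec.analysis_shape, spec.margin_px)
    rng = np.random.default_rng(seed)
    native = render_native_rgb(labels, spec.classes, spec.downsample, rng)
    phantom = Phantom(native_rgb=native, gt_labels=labels, spec=spec)

    clf = oracle_classifier(spec, seed=seed)
    config = PipelineConfig(seed=seed, class_names=spec.class_names)
    result, accuracy = run_phantom(phantom, clf, config)
    report = run_endpoints(result.class_map, config, result.tissue, gt=labels)
    return {
        "accuracy": accuracy,
        "iou": report.overlap.iou,
        "dice": report.overlap.dice,
        "estimated_area_mm2": report.tumor.area_mm2,
        "composition": report.composition.ratios if report.composition else None,
        "margin_pixels": int(report.margin.sum()),
    }
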