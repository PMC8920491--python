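"""File I/O for phantoms, superpixel maps, class maps, and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fusion import ClassMap, Status, SuperpixelLabeling
from .superpixels import SuperpixelMap
from .synthetic import Phantom

__all__ = [
    "write_phantom",
    "write_superpixel_map",
    "read_superpixel_map",
    "write_class_map",
    "read_class_map",
    "write_labeling_csv",
    "write_sample_csv",
]


def write_phantom(phantom: Phantom, out_dir, native_mpp: float = 0.22) -> dict:
    """Write a phantom as pyramidal RGB TIFF + GT label TIFF + JSON spec.

    The RGB TIFF carries the native level plus mean-pooled SubIFD levels
    down to the analysis downsample in factor-4 steps (successive ratios
    must stay small for readers to chain the levels into one pyramid).
    Returns the written paths.
    """
    from .slide_model import block_mean_pool

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slide_path = out / "slide.tiff"
    gt_path = out / "gt.tiff"
    spec_path = out / "phantom.json"

    ds = phantom.spec.downsample
    factors = []
    f = 4
    while f < ds:
        factors.append(f)
        f *= 4
    factors.append(ds)
    levels = [block_mean_pool(phantom.native_rgb, f) for f in factors]
    resolution = (10000.0 / native_mpp, 10000.0 / native_mpp)  # px per cm
    with tifffile.TiffWriter(slide_path) as tw:
        tw.write(
            phantom.native_rgb,
            subifds=len(levels),
            tile=(256, 256),
            photometric="rgb",
            resolution=resolution,
            resolutionunit="CENTIMETER",
            metadata=None,   # plain TIFF so readers detect the SubIFD pyramid
        )
        for level in levels:
            tw.write(level, subfiletype=1, tile=(256, 256), photometric="rgb")
    tifffile.imwrite(gt_path, phantom.gt_labels)

    spec = phantom.spec
    spec_path.write_text(
        json.dumps(
            {
                "classes": [
                    {"name": c.name, "h": c.h, "e": c.e, "noise_std": c.noise_std}
                    for c in spec.classes
                ],
                "region_process": spec.region_process,
                "region_scale_px": spec.region_scale_px,
                "analysis_shape": list(spec.analysis_shape),
                "downsample": spec.downsample,
                "margin_px": spec.margin_px,
                "n_fissures": spec.n_fissures,
                "fissure_width_px": spec.fissure_width_px,
                "seed": spec.seed,
            },
            indent=2,
        )
    )
    return {"slide": slide_path, "gt": gt_path, "spec": spec_path}


def write_superpixel_map(spmap: SuperpixelMap, path, extra: dict | None = None) -> None:
    """Single-channel 32-bit TIFF + JSON sidecar (background ids, sizes)."""
    path = Path(path)
    tifffile.imwrite(path, spmap.labels.astype(np.int32))
    sidecar = {
        "background_ids": sorted(spmap.background_ids),
        "sizes": {str(k): v for k, v in spmap.sizes.items()},
    }
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_superpixel_map(path) -> SuperpixelMap:
    path = Path(path)
    labels = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return SuperpixelMap(labels=labels, background_ids=frozenset(sidecar["background_ids"]))


def write_class_map(class_map: ClassMap, path) -> None:
    """8-bit single-channel TIFF + JSON legend (class codes and sentinels)."""
    path = Path(path)
    tifffile.imwrite(path, class_map.raster)
    path.with_suffix(".json").write_text(
        json.dumps({"legend": class_map.legend, "mpp": class_map.mpp}, indent=2)
    )


def read_class_map(path) -> ClassMap:
    path = Path(path)
    raster = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    names = [
        name
        for name, code in sorted(sidecar["legend"].items(), key=lambda kv: kv[1])
        if name not in ("BACKGROUND", "UNCLASSIFIED", "REJECTED")
    ]
    return ClassMap(raster=raster, class_names=tuple(names), mpp=float(sidecar["mpp"]))


def write_labeling_csv(labeling: SuperpixelLabeling, path) -> None:
    """Per-superpixel CSV: id, label, N, confidence, status."""
    rows = []
    for sp_id in sorted(labeling.records):
        rec = labeling.records[sp_id]
        rows.append(
            {
                "superpixel_id": sp_id,
                "label": labeling.class_names[rec.label] if rec.label is not None else "",
                "n_patches": rec.n,
                "confidence": rec.confidence if rec.confidence is not None else "",
                "status": rec.status.value,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_sample_csv(assignment, sample, path) -> None:
    """Selected patches as CSV (superpixel_id, patch_row, patch_col, coverage)."""
    coverage = {
        (i, j): cov
        for sp_id, patches in assignment.by_superpixel.items()
        for i, j, cov in patches
    }
    rows = [
        {"superpixel_id": sp_id, "patch_row": i, "patch_col": j, "coverage": coverage[(i, j)]}
        for sp_id in sorted(sample.selected)
        for i, j in sample.selected[sp_id]
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
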