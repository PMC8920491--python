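"""Tumor-area morphology, IoU/Dice, invasive margin, composition."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from slidecarto.config import DEFAULT_CLASS_NAMES
from slidecarto.fusion import ClassMap
from slidecarto.slide_model import ForegroundMask
from slidecarto.tumor_endpoints import composition, invasive_margin, overlap, tumor_area

from conftest import load_toy

TUMOR, MUSCLE, CONNECTIVE, MUCOSA, NECROSIS, INFLAMMATION, MUCUS = range(1, 8)


def _cmap(raster):
    return ClassMap(raster=np.asarray(raster, dtype=np.uint8), class_names=DEFAULT_CLASS_NAMES, mpp=3.54)


class TestTumorArea:
    def test_golden_toy_raster(self):
        """Committed 40x40 toy: flush necrosis and mucus merge into the
        tumor, the enclosed connective hole is filled, and the distant
        necrosis island is excluded; result equals the hand-derived mask
        (a solid rectangle minus the two interior convex corners that a
        radius-1 disk opening shaves off)."""
        toy = load_toy("tumor_toy_classes.txt")
        expected = load_toy("tumor_toy_expected_mask.txt").astype(bool)
        result = tumor_area(_cmap(toy), closing_radius=1, opening_radius=1)
        assert np.array_equal(result.mask, expected)
        assert result.components == 1

    def test_distant_necrosis_excluded(self):
        raster = np.zeros((40, 40), dtype=np.uint8)
        raster[5:15, 5:15] = TUMOR
        raster[25:30, 25:30] = NECROSIS     # 10 px away from the tumor
        result = tumor_area(_cmap(raster), closing_radius=1, opening_radius=1)
        assert not result.mask[25:30, 25:30].any()
        assert result.mask[6:14, 6:14].all()

    def test_adjacent_necrosis_included(self):
        raster = np.zeros((40, 40), dtype=np.uint8)
        raster[5:15, 5:15] = TUMOR
        raster[15:20, 5:15] = NECROSIS      # flush contact
        result = tumor_area(_cmap(raster), closing_radius=1, opening_radius=1)
        assert result.mask[16:19, 6:14].all()

    def test_empty_map(self):
        result = tumor_area(_cmap(np.zeros((20, 20))), closing_radius=1, opening_radius=1)
        assert not result.mask.any()
        assert result.area_mm2 == 0.0

    def test_enclosed_component_filled_regardless_of_class(self):
        # inflammation fully surrounded by tumor: inside the outer contour
        raster = np.zeros((30, 30), dtype=np.uint8)
        raster[5:25, 5:25] = TUMOR
        raster[12:18, 12:18] = INFLAMMATION
        result = tumor_area(_cmap(raster), closing_radius=1, opening_radius=1)
        assert result.mask[12:18, 12:18].all()

    def test_monotone_in_tumor_pixels(self):
        raster = np.zeros((40, 40), dtype=np.uint8)
        raster[10:20, 10:20] = TUMOR
        base = tumor_area(_cmap(raster), closing_radius=1, opening_radius=1).mask
        grown = raster.copy()
        grown[20:25, 10:20] = TUMOR
        bigger = tumor_area(_cmap(grown), closing_radius=1, opening_radius=1).mask
        assert np.all(bigger | ~base)

    def test_area_units(self):
        raster = np.zeros((50, 50), dtype=np.uint8)
        raster[10:40, 10:40] = TUMOR        # 900 px at 3.54 um/px
        result = tumor_area(_cmap(raster), closing_radius=0, opening_radius=0)
        assert result.area_mm2 == pytest.approx(900 * (3.54 / 1000) ** 2, abs=5e-4)

    def test_unknown_class_name_rejected(self):
        with pytest.raises(ValueError):
            tumor_area(_cmap(np.zeros((5, 5))), classes=("tumor cells", "necrosis", "slime"))


class TestOverlap:
    def test_identical_masks(self):
        mask = np.random.default_rng(0).random((20, 20)) < 0.3
        m = overlap(mask, mask)
        assert m.iou == 1.0 and m.dice == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[:5] = True
        b[5:] = True
        m = overlap(a, b)
        assert m.iou == 0.0 and m.dice == 0.0

    def test_half_overlap_arithmetic(self):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a[:10, :10] = True                  # |E| = 100
        b[5:15, :10] = True                 # |GT| = 100, intersection 50
        m = overlap(a, b)
        assert m.iou == pytest.approx(1 / 3)
        assert m.dice == pytest.approx(0.5)

    def test_dice_iou_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = rng.random((15, 15)) < rng.uniform(0.1, 0.9)
            b = rng.random((15, 15)) < rng.uniform(0.1, 0.9)
            m = overlap(a, b)
            assert m.dice == pytest.approx(2 * m.iou / (1 + m.iou), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            overlap(np.zeros((4, 4), dtype=bool), np.zeros((5, 5), dtype=bool))


def _margin_brute_force(tumor, tissue, w):
    """Two-stage construction recomputed with pairwise Euclidean distances."""
    coords = lambda m: np.argwhere(m)
    all_px = np.argwhere(np.ones_like(tumor, dtype=bool))

    d_tumor = cdist(all_px, coords(tumor)).min(axis=1).reshape(tumor.shape)
    outside = (d_tumor <= w) & tissue & ~tumor
    if not outside.any():
        return np.zeros_like(tumor)
    d_band = cdist(all_px, coords(outside)).min(axis=1).reshape(tumor.shape)
    return (d_band <= w) & tissue


class TestInvasiveMargin:
    def test_square_tumor_matches_distance_oracle(self):
        tumor = np.zeros((60, 60), dtype=bool)
        tumor[20:40, 20:40] = True
        tissue = ForegroundMask(np.ones((60, 60), dtype=bool), 220)
        w_px = 5
        band = invasive_margin(tumor, tissue, width_um=w_px * 3.54, mpp=3.54)
        oracle = _margin_brute_force(tumor, tissue.mask, w_px)
        disagreements = band ^ oracle
        assert not disagreements.any()

    def test_tumor_fills_tissue_gives_empty_margin(self):
        tissue = ForegroundMask(np.ones((30, 30), dtype=bool), 220)
        band = invasive_margin(np.ones((30, 30), dtype=bool), tissue, 50.0, 3.54)
        assert not band.any()

    def test_width_one_pixel_band_hugs_boundary(self):
        tumor = np.zeros((40, 40), dtype=bool)
        tumor[10:30, 10:30] = True
        tissue = ForegroundMask(np.ones((40, 40), dtype=bool), 220)
        band = invasive_margin(tumor, tissue, width_um=3.54, mpp=3.54)  # w = 1 px
        from scipy.ndimage import distance_transform_edt

        boundary_dist = np.minimum(
            distance_transform_edt(tumor), distance_transform_edt(~tumor)
        )
        assert band.any()
        assert boundary_dist[band].max() <= 2.0

    def test_no_tissue_gives_empty_margin(self):
        tumor = np.zeros((10, 10), dtype=bool)
        tumor[4:6, 4:6] = True
        tissue = ForegroundMask(np.zeros((10, 10), dtype=bool), 220)
        assert not invasive_margin(tumor, tissue, 10.0, 3.54).any()

    def test_margin_restricted_to_tissue(self):
        tumor = np.zeros((40, 40), dtype=bool)
        tumor[15:25, 15:25] = True
        tissue_mask = np.ones((40, 40), dtype=bool)
        tissue_mask[:, 30:] = False
        band = invasive_margin(tumor, ForegroundMask(tissue_mask, 220), 5 * 3.54, 3.54)
        assert not band[:, 30:].any()


class TestComposition:
    def test_pure_tumor_region(self):
        raster = np.full((10, 10), TUMOR, dtype=np.uint8)
        result = composition(_cmap(raster), np.ones((10, 10), dtype=bool))
        assert result.ratios == {"tumor cells": 1.0, "necrosis": 0.0, "mucus": 0.0}

    def test_mixed_region_counting(self):
        raster = np.zeros((10, 10), dtype=np.uint8)
        flat = raster.ravel()
        flat[:60] = TUMOR
        flat[60:85] = NECROSIS
        flat[85:95] = MUCUS
        flat[95:] = MUSCLE
        result = composition(_cmap(raster), np.ones((10, 10), dtype=bool))
        assert result.ratios == {"tumor cells": 0.60, "necrosis": 0.25, "mucus": 0.10}

    def test_matches_per_pixel_loop_oracle(self):
        rng = np.random.default_rng(2)
        raster = rng.integers(0, 8, size=(20, 20)).astype(np.uint8)
        region = rng.random((20, 20)) < 0.5
        result = composition(_cmap(raster), region)
        for name, code in (("tumor cells", TUMOR), ("necrosis", NECROSIS), ("mucus", MUCUS)):
            count = sum(
                1 for i in range(20) for j in range(20) if region[i, j] and raster[i, j] == code
            )
            assert result.ratios[name] == pytest.approx(count / region.sum())

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            composition(_cmap(np.ones((5, 5))), np.zeros((5, 5), dtype=bool))
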