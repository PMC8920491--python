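"""Native-resolution patch grid, coverage-based assignment, and sampling.

The classifier consumes square patches at native resolution (224 px, the
usual CNN input size).  With a 16x analysis plane each patch footprint is
an integer 14x14 block of analysis pixels, so patch-to-superpixel
assignment reduces to counting labels inside that block: a patch belongs
to the superpixel covering the largest share of its block, provided that
share reaches the coverage threshold (50%) and the superpixel is not
background.  Per superpixel, at most ``limit`` patches (default 10) are
classified - a uniform random subsample drawn from a per-superpixel RNG
stream so the selection is reproducible and independent of iteration
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .superpixels import SuperpixelMap

__all__ = [
    "PatchGrid",
    "PatchAssignment",
    "PatchSample",
    "build_grid",
    "assign_patches",
    "sample_patches",
]

DEFAULT_PATCH_SIZE = 224
DEFAULT_PATCH_LIMIT = 10
DEFAULT_COVERAGE_THRESHOLD = 0.5


@dataclass(frozen=True)
class PatchGrid:
    """Nonoverlapping tiling of a native-resolution rectangle; partial edge
    tiles are dropped."""

    patch_size: int
    origin: tuple[int, int]            # native (row, col) of tile (0, 0)
    n_rows: int
    n_cols: int

    @property
    def n_patches(self) -> int:
        return self.n_rows * self.n_cols

    def patch_origin(self, i: int, j: int) -> tuple[int, int]:
        return (self.origin[0] + i * self.patch_size, self.origin[1] + j * self.patch_size)


@dataclass
class PatchAssignment:
    """Patch -> superpixel mapping under the coverage rule.

    ``by_superpixel`` maps id -> list of (i, j, coverage); ``patch_to_id``
    is an (n_rows, n_cols) array with -1 for unassigned patches.
    """

    grid: PatchGrid
    by_superpixel: dict = field(default_factory=dict)
    patch_to_id: np.ndarray | None = None

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.by_superpixel.values())


@dataclass
class PatchSample:
    """Per-superpixel selected patch subset, N <= limit."""

    selected: dict                      # id -> list of (i, j)
    limit: int
    seed: int

    @property
    def n_selected(self) -> int:
        return sum(len(v) for v in self.selected.values())


def build_grid(bbox: tuple[int, int, int, int], patch_size: int = DEFAULT_PATCH_SIZE) -> PatchGrid:
    """Tile a half-open native-resolution bbox with nonoverlapping patches
    anchored at the bbox top-left; the edge remainder is dropped."""
    r0, c0, r1, c1 = bbox
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"empty bounding box {bbox}")
    n_rows = (r1 - r0) // patch_size
    n_cols = (c1 - c0) // patch_size
    if n_rows == 0 or n_cols == 0:
        warnings.warn(f"bounding box {bbox} smaller than one {patch_size}px patch; empty grid")
    return PatchGrid(patch_size=patch_size, origin=(r0, c0), n_rows=n_rows, n_cols=n_cols)


def assign_patches(
    grid: PatchGrid,
    spmap: SuperpixelMap,
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    downsample: int = 16,
) -> PatchAssignment:
    """Assign each patch to the superpixel covering the largest share of its
    analysis-plane block, iff that share >= ``threshold`` and the superpixel
    is not background.

    ``spmap`` is the label raster of the *cropped* analysis bbox whose
    native footprint the grid tiles, so patch (i, j) maps to block
    ``[i*b:(i+1)*b, j*b:(j+1)*b]`` with b = patch_size // downsample.
    Ties at the maximum share resolve to the lower superpixel id.
    """
    if grid.patch_size % downsample != 0:
        raise ValueError(f"patch size {grid.patch_size} not divisible by downsample {downsample}")
    b = grid.patch_size // downsample
    labels = spmap.labels
    if grid.n_rows * b > labels.shape[0] or grid.n_cols * b > labels.shape[1]:
        raise ValueError(
            f"grid footprint {(grid.n_rows * b, grid.n_cols * b)} exceeds "
            f"superpixel raster {labels.shape}: misaligned inputs"
        )
    patch_to_id = np.full((grid.n_rows, grid.n_cols), -1, dtype=np.int64)
    by_superpixel: dict[int, list] = {}
    if grid.n_patches == 0:
        return PatchAssignment(grid=grid, by_superpixel=by_superpixel, patch_to_id=patch_to_id)

    # reshape into (n_rows, n_cols, b*b) blocks, then count labels per block
    blocks = labels[: grid.n_rows * b, : grid.n_cols * b]
    blocks = blocks.reshape(grid.n_rows, b, grid.n_cols, b).swapaxes(1, 2).reshape(
        grid.n_rows, grid.n_cols, b * b
    )
    block_area = b * b
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            counts = np.bincount(blocks[i, j])
            best = int(counts.argmax())      # argmax -> lowest id on ties
            share = counts[best] / block_area
            if best == 0 or share < threshold or best in spmap.background_ids:
                continue
            patch_to_id[i, j] = best
            by_superpixel.setdefault(best, []).append((i, j, float(share)))
    return PatchAssignment(grid=grid, by_superpixel=by_superpixel, patch_to_id=patch_to_id)


def sample_patches(
    assignment: PatchAssignment, limit: int = DEFAULT_PATCH_LIMIT, seed: int = 0
) -> PatchSample:
    """Select at most ``limit`` patches per superpixel, uniformly at random
    without replacement.  Each superpixel draws from its own RNG stream
    (seeded by (seed, id)), so sampling is independent of iteration order.
    """
    if limit < 1:
        raise ValueError("patch limit must be >= 1")
    selected: dict[int, list] = {}
    for sp_id, patches in assignment.by_superpixel.items():
        coords = [(i, j) for i, j, _ in patches]
        if len(coords) <= limit:
            selected[sp_id] = list(coords)
        else:
            rng = np.random.default_rng([seed, sp_id])
            idx = rng.choice(len(coords), size=limit, replace=False)
            selected[sp_id] = [coords[t] for t in sorted(idx)]
    return PatchSample(selected=selected, limit=limit, seed=seed)
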