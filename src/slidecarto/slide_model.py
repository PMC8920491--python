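"""Pyramidal slide abstraction, foreground detection, and tissue bounding box.

A whole-slide image is a multi-resolution pyramid; analysis runs on a
coarse plane (16x downsampled, nominally 3.54 um/px for a 0.22 um/px
native scan) while classification patches are read at native resolution.
The pyramid object hides where the pixels come from: an in-memory array
(phantoms, tests) or a tiled pyramidal TIFF read lazily through tifffile.

Coordinates are 0-based, row-major; rectangles are half-open
``(row0, col0, row1, col1)``.  Level 0 is native resolution.  Missing
pyramid levels are synthesized from the nearest finer level by integer
block averaging (mean pooling), which is exact for integer factor ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SlidePlane",
    "SlidePyramid",
    "ForegroundMask",
    "NoTissueError",
    "foreground_mask",
    "tissue_bounding_box",
    "block_mean_pool",
]

#: Default intensity above which a pixel counts as white background
#: (applied to min(R,G,B): a pixel is white only if all channels are bright).
DEFAULT_WHITE_THRESHOLD = 220


class NoTissueError(ValueError):
    """Raised when a foreground mask contains no tissue pixels."""


@dataclass
class SlidePlane:
    """One resolution level: an RGB raster plus its physical scale."""

    pixels: np.ndarray
    mpp: float
    downsample: float = 1.0

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        if pixels.ndim != 3 or pixels.shape[2] != 3:
            raise ValueError(f"plane must be an RGB raster (H, W, 3), got {pixels.shape}")
        self.pixels = pixels

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def block_mean_pool(raster: np.ndarray, factor: int) -> np.ndarray:
    """Mean-pool an image by an integer factor (trailing remainder cropped)."""
    if factor < 1:
        raise ValueError("pooling factor must be >= 1")
    if factor == 1:
        return raster
    h, w = raster.shape[:2]
    hc, wc = (h // factor) * factor, (w // factor) * factor
    if hc == 0 or wc == 0:
        raise ValueError(f"raster {raster.shape} smaller than pooling factor {factor}")
    cropped = raster[:hc, :wc].astype(np.float32)
    pooled = cropped.reshape(hc // factor, factor, wc // factor, factor, -1).mean(axis=(1, 3))
    pooled = pooled.reshape(hc // factor, wc // factor, *raster.shape[2:])
    if np.issubdtype(raster.dtype, np.integer):
        return np.clip(np.rint(pooled), 0, 255).astype(raster.dtype)
    return pooled.astype(raster.dtype)


class SlidePyramid:
    """Multi-resolution RGB slide with lazy region reads.

    Stored levels have strictly increasing integer downsample factors with
    level 0 at factor 1.  ``select_plane`` materializes a full plane at a
    requested factor; ``read_region`` reads a native-resolution window
    without materializing the whole level (the patch-read path).
    """

    def __init__(self, level_readers, downsamples, native_mpp: float):
        downsamples = [int(d) for d in downsamples]
        if downsamples[0] != 1:
            raise ValueError("level 0 must have downsample factor 1")
        if any(b <= a for a, b in zip(downsamples, downsamples[1:])):
            raise ValueError("downsample factors must be strictly increasing")
        self._readers = list(level_readers)
        self.downsamples = downsamples
        self.native_mpp = float(native_mpp)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_array(cls, native: np.ndarray, native_mpp: float) -> "SlidePyramid":
        native = np.ascontiguousarray(native)
        if native.ndim != 3 or native.shape[2] != 3:
            raise ValueError("native raster must be (H, W, 3)")
        return cls([_ArrayLevel(native)], [1], native_mpp)

    @classmethod
    def from_tiff(cls, path, native_mpp: float | None = None) -> "SlidePyramid":
        """Open a (possibly pyramidal) TIFF.  Levels are discovered from the
        first series; sub-resolutions are accessed lazily through zarr."""
        import tifffile
        import zarr

        tif = tifffile.TiffFile(str(path))
        series = tif.series[0]
        levels = series.levels if series.is_pyramidal else [series]
        base_h, base_w = levels[0].shape[:2]
        readers, downsamples = [], []
        for lvl_index, lvl in enumerate(levels):
            h = lvl.shape[0]
            factor = int(round(base_h / h))
            store = series.aszarr(level=lvl_index) if series.is_pyramidal else series.aszarr()
            readers.append(_ZarrLevel(zarr.open(store, mode="r")))
            downsamples.append(factor)
        if native_mpp is None:
            native_mpp = _mpp_from_tiff(tif)
        return cls(readers, downsamples, native_mpp)

    # -- geometry ----------------------------------------------------------

    def level_shape(self, level_index: int) -> tuple[int, int]:
        return self._readers[level_index].shape

    @property
    def native_shape(self) -> tuple[int, int]:
        return self.level_shape(0)

    def _finest_source(self, downsample: int) -> tuple[int, int]:
        """Index of the finest stored level from which ``downsample`` can be
        synthesized by integer pooling, plus the residual pooling factor."""
        best = None
        for idx, d in enumerate(self.downsamples):
            if downsample % d == 0:
                best = (idx, downsample // d)
        if best is None:
            raise ValueError(f"downsample {downsample} not reachable from levels {self.downsamples}")
        # prefer the coarsest exact level (smallest residual pooling)
        for idx in reversed(range(len(self.downsamples))):
            if downsample % self.downsamples[idx] == 0:
                return idx, downsample // self.downsamples[idx]
        return best

    # -- pixel access ------------------------------------------------------

    def select_plane(self, downsample: int) -> SlidePlane:
        """Materialize the full plane at an integer downsample factor."""
        downsample = int(downsample)
        if downsample < 1:
            raise ValueError("requested factor is finer than native resolution")
        idx, residual = self._finest_source(downsample)
        raster = self._readers[idx].read_full()
        if residual > 1:
            raster = block_mean_pool(raster, residual)
        return SlidePlane(pixels=raster, mpp=self.native_mpp * downsample, downsample=downsample)

    def read_region(self, row0: int, col0: int, height: int, width: int) -> np.ndarray:
        """Read a native-resolution RGB window (half-open row/col bounds)."""
        return self._readers[0].read_window(row0, col0, height, width)


class _ArrayLevel:
    def __init__(self, arr: np.ndarray):
        self._arr = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self._arr.shape[:2]

    def read_full(self) -> np.ndarray:
        return self._arr

    def read_window(self, r0, c0, h, w) -> np.ndarray:
        return np.asarray(self._arr[r0 : r0 + h, c0 : c0 + w])


class _ZarrLevel:
    def __init__(self, za):
        self._za = za

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self._za.shape[:2])

    def read_full(self) -> np.ndarray:
        return np.asarray(self._za)

    def read_window(self, r0, c0, h, w) -> np.ndarray:
        return np.asarray(self._za[r0 : r0 + h, c0 : c0 + w])


def _mpp_from_tiff(tif) -> float:
    """Best-effort microns-per-pixel from TIFF resolution tags; falls back
    to 1.0 when the file carries no physical scale."""
    try:
        page = tif.pages[0]
        unit = page.tags.get("ResolutionUnit")
        xres = page.tags.get("XResolution")
        if xres is not None and unit is not None:
            num, den = xres.value
            per_unit = num / den
            if per_unit > 0:
                unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit.value))
                if unit_um:
                    return unit_um / per_unit
    except Exception:
        pass
    return 1.0


@dataclass
class ForegroundMask:
    """Boolean tissue mask at analysis resolution (True = tissue)."""

    mask: np.ndarray
    white_threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def foreground_mask(plane: SlidePlane, white_threshold: float = DEFAULT_WHITE_THRESHOLD) -> ForegroundMask:
    """Tissue detection by white thresholding.

    A pixel is background iff ``min(R, G, B) >= white_threshold`` - i.e. it
    is white only when *all* channels are bright, so strongly colored but
    bright pixels still count as tissue.
    """
    white = plane.pixels.min(axis=2) >= white_threshold
    return ForegroundMask(mask=~white, white_threshold=white_threshold)


def tissue_bounding_box(fg: ForegroundMask) -> tuple[int, int, int, int]:
    """Tightest half-open rectangle containing all tissue pixels."""
    rows = np.flatnonzero(fg.mask.any(axis=1))
    cols = np.flatnonzero(fg.mask.any(axis=0))
    if rows.size == 0:
        raise NoTissueError("foreground mask contains no tissue pixels")
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1
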