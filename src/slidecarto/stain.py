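"""Optical-density conversion and stain color deconvolution.

Brightfield histology follows the Beer-Lambert law: the transmitted
intensity of a stained pixel is ``I = I0 * exp(-c . M)`` where ``c`` holds
per-stain concentrations and the rows of ``M`` are unit optical-density
(OD) vectors characteristic of each dye.  Converting an RGB image to OD
space therefore makes pixel values *linear* in stain concentration, and a
3x3 solve per pixel ("color deconvolution", Ruifrok & Johnston style)
unmixes the image into per-stain channels.  Downstream, superpixel
clustering runs on the hematoxylin/eosin channels instead of a generic
color space, which is what makes the segmentation stain-aware.

Conventions: natural logarithm for OD; intensities are floored at 1/255 of
the background intensity before the log so a pure-black pixel maps to a
large finite OD instead of infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainMatrix",
    "StainChannels",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "reconstruct_rgb",
    "hed_perturb",
]

#: Ruifrok-Johnston reference OD vectors (rows: stain, cols: R, G, B).
_RJ_HEMATOXYLIN = (0.650, 0.704, 0.286)
_RJ_EOSIN = (0.072, 0.990, 0.105)
_RJ_DAB = (0.268, 0.570, 0.776)

#: Floor (as a fraction of the background intensity) applied before the log.
INTENSITY_FLOOR_FRACTION = 1.0 / 255.0


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length stain vector")
    return v / n


@dataclass(frozen=True)
class StainMatrix:
    """A 3x3 basis of unit-norm stain OD vectors (one stain per row)."""

    vectors: np.ndarray
    names: tuple[str, str, str]

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        if vectors.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {vectors.shape}")
        if len(self.names) != 3:
            raise ValueError("exactly three stain names required")
        norms = np.linalg.norm(vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain vectors must be unit-norm, norms={norms}")
        if np.linalg.cond(vectors) > 1e8:
            raise ValueError("stain matrix is singular or near-singular")
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.vectors)

    @classmethod
    def from_rows(cls, rows, names) -> "StainMatrix":
        """Build from (possibly non-unit) rows; a None third row is completed
        orthogonally to span RGB space (the 'residual' stain)."""
        rows = list(rows)
        names = list(names)
        if len(rows) == 2 or rows[2] is None:
            a = _unit(np.asarray(rows[0], dtype=float))
            b = _unit(np.asarray(rows[1], dtype=float))
            rows = [a, b, np.cross(a, b)]
            if len(names) == 2:
                names = names + ["residual"]
        vectors = np.stack([_unit(np.asarray(r, dtype=float)) for r in rows])
        return cls(vectors=vectors, names=tuple(names))

    @classmethod
    def he(cls) -> "StainMatrix":
        """Standard Ruifrok-Johnston H&E basis with an orthogonal residual."""
        return cls.from_rows([_RJ_HEMATOXYLIN, _RJ_EOSIN, None], ["H", "E"])

    @classmethod
    def h_dab(cls) -> "StainMatrix":
        """Hematoxylin-DAB basis for IHC sections."""
        return cls.from_rows([_RJ_HEMATOXYLIN, _RJ_DAB, None], ["H", "DAB"])


@dataclass
class StainChannels:
    """Per-pixel stain concentration rasters, shape ``(..., n_stains)``."""

    concentrations: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.concentrations, dtype=float)
        if arr.shape[-1] != len(self.names):
            raise ValueError("channel count does not match stain names")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite stain concentrations")
        self.concentrations = arr
        self.names = tuple(self.names)

    def channel(self, name: str) -> np.ndarray:
        return self.concentrations[..., self.names.index(name)]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.concentrations.shape[:-1]


def rgb_to_od(plane: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Convert an RGB raster to optical density.

    OD = -ln(I / I0) per channel, with I floored at ``I0/255`` so the result
    is finite everywhere.  A pixel at background intensity has OD 0.
    """
    plane = np.asarray(plane)
    if plane.ndim < 1 or plane.shape[-1] != 3:
        raise ValueError(f"expected an RGB raster with trailing dim 3, got shape {plane.shape}")
    floor = background_intensity * INTENSITY_FLOOR_FRACTION
    intensity = np.clip(plane.astype(np.float32), floor, background_intensity)
    od = -np.log(intensity / np.float32(background_intensity))
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (up to the intensity floor), as uint8."""
    od = np.asarray(od, dtype=np.float32)
    intensity = background_intensity * np.exp(-od)
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def deconvolve(od: np.ndarray, m: StainMatrix, clip_negative: bool = True) -> StainChannels:
    """Unmix an OD raster into per-stain concentration channels.

    Solves ``od = c @ m.vectors`` exactly per pixel (the basis is square and
    invertible, so the least-squares solution is the linear solve).  Small
    negative concentrations - noise outside the stain simplex - are capped
    at zero unless ``clip_negative`` is False.
    """
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != 3:
        raise ValueError(f"OD raster must have trailing dim 3, got {od.shape}")
    conc = od @ m.inverse
    if clip_negative:
        conc = np.maximum(conc, 0.0)
    return StainChannels(concentrations=conc, names=m.names)


def reconstruct_rgb(
    channels: StainChannels, m: StainMatrix, background_intensity: float = 255.0
) -> np.ndarray:
    """Render stain concentrations back to RGB via Beer-Lambert."""
    if channels.names != m.names:
        raise ValueError(f"stain names {channels.names} do not match matrix {m.names}")
    od = channels.concentrations @ m.vectors
    return od_to_rgb(od, background_intensity=background_intensity)


def hed_perturb(channels: StainChannels, scale, shift) -> StainChannels:
    """Per-stain affine perturbation ``c' = c * scale + shift``.

    Emulates slide-to-slide staining-intensity variation (the usual H&E
    augmentation trick) for user classifiers and phantom variation.
    """
    scale = np.broadcast_to(np.asarray(scale, dtype=float), (len(channels.names),))
    shift = np.broadcast_to(np.asarray(shift, dtype=float), (len(channels.names),))
    if np.any(scale <= 0):
        raise ValueError("stain scales must be positive")
    return StainChannels(
        concentrations=channels.concentrations * scale + shift,
        names=channels.names,
    )
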