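"""Stain-realistic slide phantoms with exact ground truth, and a noisy
nearest-centroid oracle classifier.

A phantom is drawn in two steps.  First a tissue-class label map is
generated at analysis resolution by a region process - Voronoi cells of a
chosen linear scale, or thresholded smoothed noise ("blobs") - over a
configurable class list; a white frame and a few white fissure lines
emulate the slide background and tissue cracks.  Second, the label map is
upsampled to native resolution (16x) and rendered to RGB through the
Beer-Lambert law: each class has mean hematoxylin/eosin optical
densities, per-pixel Gaussian texture noise is added to the
concentrations, and the stain matrix turns concentrations into colors.
Because rendering and analysis share the same deconvolution basis, stain
unmixing recovers the class concentrations up to quantization, and the
ground-truth raster is exact by construction.

The oracle classifier mimics a trained patch CNN: it measures a patch's
mean stain optical density, scores classes by distance to the class
centroids, and emits a temperature-scaled softmax.  A configurable noise
model (symmetric label noise or a full confusion table) corrupts a
fraction of patch outputs, emulating CNN error structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from . import stain

__all__ = [
    "TissueClass",
    "PhantomSpec",
    "OracleNoise",
    "Phantom",
    "default_classes",
    "make_phantom",
    "render_native_rgb",
    "oracle_classifier",
    "OracleClassifier",
]

WHITE = 255


@dataclass(frozen=True)
class TissueClass:
    """One renderable tissue class: mean H/E optical densities plus the
    std of the per-pixel concentration texture noise."""

    name: str
    h: float
    e: float
    noise_std: float = 0.03

    def __post_init__(self) -> None:
        if self.h < 0 or self.e < 0:
            raise ValueError("stain densities must be nonnegative")


def default_classes() -> tuple[TissueClass, ...]:
    """Seven classes mirroring a colon-resection legend, with distinct
    (H, E) density pairs: nuclear-dense classes high in hematoxylin,
    stromal/eosinophilic classes high in eosin, mucus nearly unstained."""
    return (
        TissueClass("tumor cells", h=0.90, e=0.45),
        TissueClass("muscle", h=0.30, e=0.85),
        TissueClass("connective/adipose", h=0.15, e=0.45),
        TissueClass("mucosa", h=0.65, e=0.60),
        TissueClass("necrosis", h=0.50, e=0.95),
        TissueClass("inflammation", h=1.10, e=0.25),
        TissueClass("mucus", h=0.20, e=0.15),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom slide."""

    classes: tuple = field(default_factory=default_classes)
    region_process: str = "voronoi"       # or "blobs"
    region_scale_px: int = 60             # linear region scale, analysis px
    analysis_shape: tuple[int, int] = (224, 224)
    downsample: int = 16
    margin_px: int = 8                    # white frame width, analysis px
    n_fissures: int = 2
    fissure_width_px: int = 2
    boundary_blur_px: float = 3.0         # gradual class transitions (~10 um at 3.54 um/px)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("at least two tissue classes required")
        if self.region_scale_px <= 0:
            raise ValueError("region scale must be positive")
        if self.region_scale_px >= min(self.analysis_shape):
            raise ValueError("region scale must be smaller than the image")

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.classes)

    @property
    def native_shape(self) -> tuple[int, int]:
        return (self.analysis_shape[0] * self.downsample, self.analysis_shape[1] * self.downsample)


@dataclass(frozen=True)
class OracleNoise:
    """Noise model applied to oracle patch outputs.

    ``symmetric``: with probability epsilon, replace the output by a
    smoothed one-hot on a uniformly drawn class (possibly the clean one,
    so epsilon = 1 yields chance-level 1/K accuracy).  ``confusion``: the
    replacement class is drawn from the confusion row of the clean
    prediction (rows must sum to 1; diagonal mass keeps the prediction).
    """

    mode: str = "none"                    # none | symmetric | confusion
    epsilon: float = 0.0
    confusion: np.ndarray | None = None
    temperature: float = 0.02

    def __post_init__(self) -> None:
        if self.mode not in ("none", "symmetric", "confusion"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.mode == "symmetric" and not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        if self.mode == "confusion":
            if self.confusion is None:
                raise ValueError("confusion mode requires a confusion table")
            table = np.asarray(self.confusion, dtype=float)
            if table.ndim != 2 or table.shape[0] != table.shape[1]:
                raise ValueError("confusion table must be square")
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("confusion rows must sum to 1")
            object.__setattr__(self, "confusion", table)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class Phantom:
    """A rendered phantom: native RGB, analysis-resolution ground truth
    (class codes 1..K, 0 = background), and the generating spec."""

    native_rgb: np.ndarray
    gt_labels: np.ndarray
    spec: PhantomSpec


def _voronoi_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.analysis_shape
    n_sites = max(2, round(h * w / spec.region_scale_px**2))
    sites = rng.uniform(0, [h, w], size=(n_sites, 2))
    k = len(spec.classes)
    # cycle through the first K sites so every class is present when possible
    site_class = np.concatenate(
        [np.arange(min(k, n_sites)), rng.integers(0, k, size=max(0, n_sites - k))]
    )
    rr, cc = np.mgrid[0:h, 0:w]
    _, nearest = cKDTree(sites).query(np.column_stack([rr.ravel(), cc.ravel()]))
    return (site_class[nearest].reshape(h, w) + 1).astype(np.uint8)


def _blob_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.analysis_shape
    k = len(spec.classes)
    fields = np.stack(
        [gaussian_filter(rng.standard_normal((h, w)), sigma=spec.region_scale_px / 2) for _ in range(k)]
    )
    return (fields.argmax(axis=0) + 1).astype(np.uint8)


def _apply_background(labels: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = labels.shape
    out = labels.copy()
    m = spec.margin_px
    if m > 0:
        out[:m, :] = 0
        out[-m:, :] = 0
        out[:, :m] = 0
        out[:, -m:] = 0
    # fissures: straight white cracks across the tissue
    for _ in range(spec.n_fissures):
        if rng.random() < 0.5:
            r = rng.integers(h // 4, 3 * h // 4)
            out[max(0, r - spec.fissure_width_px // 2) : r + (spec.fissure_width_px + 1) // 2, :] = 0
        else:
            c = rng.integers(w // 4, 3 * w // 4)
            out[:, max(0, c - spec.fissure_width_px // 2) : c + (spec.fissure_width_px + 1) // 2] = 0
    return out


def render_native_rgb(
    labels: np.ndarray,
    classes,
    downsample: int,
    rng: np.random.Generator,
    matrix: stain.StainMatrix | None = None,
    boundary_blur_px: float = 0.0,
) -> np.ndarray:
    """Render an analysis-resolution label map (0 = white background) to a
    native-resolution RGB raster via Beer-Lambert with texture noise.

    With ``boundary_blur_px`` > 0 the per-class densities are blended
    across region boundaries (Gaussian weights at analysis scale),
    emulating the gradual tissue transitions of real sections - tumor
    infiltration fronts and inflammation gradients are not step edges.
    Background blends toward white the same way.  The label map itself
    stays sharp (annotations are crisp even where tissue is not).
    """
    matrix = matrix or stain.StainMatrix.he()
    classes = tuple(classes)
    mean_h = np.array([0.0] + [c.h for c in classes], dtype=np.float32)
    mean_e = np.array([0.0] + [c.e for c in classes], dtype=np.float32)
    noise = np.array([0.0] + [c.noise_std for c in classes], dtype=np.float32)

    up = np.repeat(np.repeat(labels, downsample, axis=0), downsample, axis=1)
    if boundary_blur_px > 0:
        h_map = np.zeros(labels.shape, dtype=np.float32)
        e_map = np.zeros(labels.shape, dtype=np.float32)
        n_map = np.zeros(labels.shape, dtype=np.float32)
        wsum = np.zeros(labels.shape, dtype=np.float32)
        for code in range(len(classes) + 1):
            w = gaussian_filter((labels == code).astype(np.float32), boundary_blur_px)
            h_map += w * mean_h[code]
            e_map += w * mean_e[code]
            n_map += w * noise[code]
            wsum += w
        h_map /= wsum
        e_map /= wsum
        n_map /= wsum
        base_h = np.repeat(np.repeat(h_map, downsample, axis=0), downsample, axis=1)
        base_e = np.repeat(np.repeat(e_map, downsample, axis=0), downsample, axis=1)
        base_n = np.repeat(np.repeat(n_map, downsample, axis=0), downsample, axis=1)
    else:
        base_h, base_e, base_n = mean_h[up], mean_e[up], noise[up]
    c_h = base_h + base_n * rng.standard_normal(up.shape, dtype=np.float32)
    c_e = base_e + base_n * rng.standard_normal(up.shape, dtype=np.float32)
    np.maximum(c_h, 0.0, out=c_h)
    np.maximum(c_e, 0.0, out=c_e)

    vectors = matrix.vectors.astype(np.float32)
    od = c_h[..., None] * vectors[0] + c_e[..., None] * vectors[1]
    rgb = stain.od_to_rgb(od)
    if boundary_blur_px <= 0:
        rgb[up == 0] = WHITE
    return rgb


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Draw and render one phantom; bit-deterministic under the spec seed."""
    rng = np.random.default_rng(spec.seed)
    if spec.region_process == "voronoi":
        labels = _voronoi_labels(spec, rng)
    elif spec.region_process == "blobs":
        labels = _blob_labels(spec, rng)
    else:
        raise ValueError(f"unknown region process {spec.region_process!r}")
    labels = _apply_background(labels, spec, rng)
    native = render_native_rgb(
        labels, spec.classes, spec.downsample, rng, boundary_blur_px=spec.boundary_blur_px
    )
    return Phantom(native_rgb=native, gt_labels=labels, spec=spec)


class OracleClassifier:
    """Nearest-centroid patch classifier over mean stain optical density.

    For each patch: mean OD -> deconvolved (H, E) -> distances to the
    class centroids -> softmax(-d / temperature).  The noise model then
    corrupts a fraction of outputs.  Seeded at construction; with a fixed
    patch order the output stream is reproducible.
    """

    def __init__(
        self,
        classes,
        noise: OracleNoise | None = None,
        matrix: stain.StainMatrix | None = None,
        seed: int = 0,
        pixel_stride: int = 2,
    ):
        self.classes = tuple(classes)
        self.class_names = tuple(c.name for c in self.classes)
        self.noise = noise or OracleNoise()
        self.matrix = matrix or stain.StainMatrix.he()
        self._rng = np.random.default_rng(seed)
        self._stride = pixel_stride
        self._centroids = np.array([[c.h, c.e] for c in self.classes], dtype=float)
        if self.noise.mode == "confusion" and self.noise.confusion.shape[0] != len(self.classes):
            raise ValueError("confusion table size does not match the class list")

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches)
        if patches.ndim != 4 or patches.shape[-1] != 3:
            raise ValueError(f"expected a (N, h, w, 3) patch batch, got {patches.shape}")
        sub = patches[:, :: self._stride, :: self._stride, :]
        od = stain.rgb_to_od(sub).mean(axis=(1, 2))                     # (N, 3)
        conc = od @ self.matrix.inverse                                  # (N, 3)
        he = np.maximum(conc[:, :2], 0.0)
        d = np.linalg.norm(he[:, None, :] - self._centroids[None, :, :], axis=2)
        logits = -d / self.noise.temperature
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        return self._corrupt(probs)

    def _corrupt(self, probs: np.ndarray) -> np.ndarray:
        if self.noise.mode == "none" or len(probs) == 0:
            return probs
        k = probs.shape[1]
        clean = probs.argmax(axis=1)
        if self.noise.mode == "symmetric":
            flip = self._rng.random(len(probs)) < self.noise.epsilon
            replacement = self._rng.integers(0, k, size=len(probs))
        else:  # confusion
            replacement = np.array(
                [self._rng.choice(k, p=self.noise.confusion[c]) for c in clean]
            )
            flip = replacement != clean
        smoothing = 0.1
        out = probs.copy()
        if np.any(flip):
            one_hot = np.full((int(flip.sum()), k), smoothing / k)
            one_hot[np.arange(int(flip.sum())), replacement[flip]] += 1.0 - smoothing
            out[flip] = one_hot
        return out


def oracle_classifier(
    spec: PhantomSpec, noise: OracleNoise | None = None, seed: int = 0
) -> OracleClassifier:
    """Oracle bound to a phantom spec's class list and stain basis."""
    return OracleClassifier(spec.classes, noise=noise, seed=seed)
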