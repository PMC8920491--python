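"""Patch-to-superpixel label fusion, vote confidence, and rejection.

Each classified patch yields a softmax probability vector over the tissue
classes.  A superpixel's fused distribution is the plain mean of its patch
vectors and its label the argmax of that mean.  Separately, a hard-vote
confidence is computed: each patch votes for its own argmax class, and

    Cdiffvotes = (v1 - v2) / N

where v1 and v2 are the two largest vote counts among the N patches.  The
measure is 1 iff the votes are unanimous and 0 iff the top two classes
tie.  Superpixels with confidence strictly below a threshold (default
0.1) are assigned a rejection sentinel and excluded from the rendered
class map and from evaluation; the fused label is retained internally.

Sentinel codes in rendered class maps: 0 = background, 254 = unclassified
(no patch reached the coverage rule), 255 = rejected.  Tissue classes use
codes 1..K in class-list order.  Argmax ties break to the lowest class
index everywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .superpixels import SuperpixelMap

__all__ = [
    "BACKGROUND",
    "UNCLASSIFIED",
    "REJECTED",
    "Status",
    "ProtocolError",
    "ClassMap",
    "SuperpixelRecord",
    "SuperpixelLabeling",
    "classify_patches",
    "fuse",
    "vote_confidence",
    "build_labeling",
    "apply_rejection",
    "render_class_map",
]

BACKGROUND = 0
UNCLASSIFIED = 254
REJECTED = 255

_PROB_ATOL = 1e-6


class Status(enum.Enum):
    LABELED = "labeled"
    REJECTED = "rejected"
    UNCLASSIFIED = "unclassified"
    BACKGROUND = "background"


class ProtocolError(ValueError):
    """A classifier violated the patch-probability protocol."""


@dataclass(frozen=True)
class SuperpixelRecord:
    """Fused classification state of one superpixel."""

    label: int | None              # class index into the class list, or None
    mean_vector: np.ndarray | None
    n: int
    votes: np.ndarray | None       # per-class argmax counts, sums to n
    confidence: float | None       # Cdiffvotes in [0, 1]
    status: Status


@dataclass
class SuperpixelLabeling:
    """id -> SuperpixelRecord for every superpixel of a map."""

    records: dict
    class_names: tuple[str, ...]

    def __getitem__(self, sp_id: int) -> SuperpixelRecord:
        return self.records[sp_id]

    def ids_with_status(self, status: Status) -> list[int]:
        return sorted(i for i, r in self.records.items() if r.status is status)


def _validate_probs(probs: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim == 1:
        probs = probs[None, :]
    if probs.ndim != 2:
        raise ProtocolError(f"probability batch must be 2-D, got shape {probs.shape}")
    if n_classes is not None and probs.shape[1] != n_classes:
        raise ProtocolError(f"expected {n_classes} classes, got {probs.shape[1]}")
    if np.any(probs < 0):
        raise ProtocolError("negative class probabilities")
    sums = probs.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=_PROB_ATOL):
        raise ProtocolError(f"probability rows must sum to 1 (max deviation {np.abs(sums - 1).max():.3g})")
    return probs


def classify_patches(classifier, patches: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Run a patch-probability classifier on a batch of RGB patches.

    ``classifier`` must expose ``predict_proba(batch) -> (N, K)``; the
    output order matches the input order and every row is validated as a
    probability vector.  An empty batch yields an empty (0, K) array.
    """
    patches = np.asarray(patches)
    if len(patches) == 0:
        k = n_classes if n_classes is not None else len(getattr(classifier, "class_names", ()))
        return np.zeros((0, k), dtype=float)
    probs = classifier.predict_proba(patches)
    probs = _validate_probs(probs, n_classes)
    if len(probs) != len(patches):
        raise ProtocolError(f"classifier returned {len(probs)} vectors for {len(patches)} patches")
    return probs


def fuse(probs: np.ndarray) -> tuple[int, np.ndarray]:
    """Mean-softmax fusion: average the patch vectors and take the argmax.

    Returns ``(label_index, mean_vector)``.  Permutation-invariant and
    invariant to duplicating the whole patch set.
    """
    probs = _validate_probs(probs)
    if len(probs) == 0:
        raise ValueError("cannot fuse an empty patch list")
    mean_vector = probs.mean(axis=0)
    return int(mean_vector.argmax()), mean_vector


def vote_confidence(probs: np.ndarray) -> float:
    """Vote-difference confidence (v1 - v2) / N over hard patch votes."""
    probs = _validate_probs(probs)
    if len(probs) == 0:
        raise ValueError("cannot score an empty patch list")
    votes = np.bincount(probs.argmax(axis=1), minlength=probs.shape[1])
    top_two = np.sort(votes)[::-1][:2]
    v2 = top_two[1] if len(top_two) > 1 else 0
    return float((top_two[0] - v2) / len(probs))


def build_labeling(
    spmap: SuperpixelMap,
    probs_by_superpixel: dict,
    class_names,
) -> SuperpixelLabeling:
    """Assemble per-superpixel records from per-superpixel patch vectors.

    Superpixels absent from ``probs_by_superpixel`` (no assigned patches)
    become UNCLASSIFIED; background superpixels become BACKGROUND.
    """
    class_names = tuple(class_names)
    k = len(class_names)
    records: dict[int, SuperpixelRecord] = {}
    for sp_id in spmap.ids:
        if sp_id in spmap.background_ids:
            records[sp_id] = SuperpixelRecord(None, None, 0, None, None, Status.BACKGROUND)
            continue
        probs = probs_by_superpixel.get(sp_id)
        if probs is None or len(probs) == 0:
            records[sp_id] = SuperpixelRecord(None, None, 0, None, None, Status.UNCLASSIFIED)
            continue
        probs = _validate_probs(probs, k)
        label, mean_vector = fuse(probs)
        votes = np.bincount(probs.argmax(axis=1), minlength=k)
        records[sp_id] = SuperpixelRecord(
            label=label,
            mean_vector=mean_vector,
            n=len(probs),
            votes=votes,
            confidence=vote_confidence(probs),
            status=Status.LABELED,
        )
    return SuperpixelLabeling(records=records, class_names=class_names)


def apply_rejection(labeling: SuperpixelLabeling, threshold: float = 0.1) -> SuperpixelLabeling:
    """Reject every labeled superpixel with confidence strictly below
    ``threshold`` (a superpixel at exactly the threshold is kept).  The
    fused label is retained in the record; only the status changes."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"rejection threshold must be in [0, 1], got {threshold}")
    records = {}
    for sp_id, rec in labeling.records.items():
        if rec.status is Status.LABELED and rec.confidence < threshold:
            rec = replace(rec, status=Status.REJECTED)
        records[sp_id] = rec
    return SuperpixelLabeling(records=records, class_names=labeling.class_names)


@dataclass
class ClassMap:
    """Per-pixel class raster at analysis resolution.

    ``raster`` holds class codes 1..K plus the sentinels; ``class_names``
    fixes the code order; ``mpp`` is the physical scale of one pixel.
    """

    raster: np.ndarray
    class_names: tuple[str, ...]
    mpp: float

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=np.uint8)
        self.class_names = tuple(self.class_names)

    @property
    def legend(self) -> dict:
        legend = {name: i + 1 for i, name in enumerate(self.class_names)}
        legend["BACKGROUND"] = BACKGROUND
        legend["UNCLASSIFIED"] = UNCLASSIFIED
        legend["REJECTED"] = REJECTED
        return legend

    def code(self, name: str) -> int:
        return self.class_names.index(name) + 1


def render_class_map(
    spmap: SuperpixelMap, labeling: SuperpixelLabeling, mpp: float
) -> ClassMap:
    """Paint every pixel with its superpixel's fused class code (or a
    sentinel).  Raster positions with label 0 (outside the tissue bounding
    box) render as background."""
    max_id = int(spmap.labels.max(initial=0))
    lut = np.full(max_id + 1, BACKGROUND, dtype=np.uint8)
    for sp_id in spmap.ids:
        rec = labeling.records.get(sp_id)
        if rec is None:
            raise KeyError(f"superpixel {sp_id} present in map but missing from labeling")
        if rec.status is Status.LABELED:
            lut[sp_id] = rec.label + 1
        elif rec.status is Status.REJECTED:
            lut[sp_id] = REJECTED
        elif rec.status is Status.UNCLASSIFIED:
            lut[sp_id] = UNCLASSIFIED
        else:
            lut[sp_id] = BACKGROUND
    return ClassMap(raster=lut[spmap.labels], class_names=labeling.class_names, mpp=mpp)
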