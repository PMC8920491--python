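"""Pipeline configuration: defaults, validation, (de)serialization."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from . import stain
from .slide_model import DEFAULT_WHITE_THRESHOLD
from .superpixels import SuperpixelConfig

__all__ = ["PipelineConfig"]

DEFAULT_CLASS_NAMES = (
    "tumor cells",
    "muscle",
    "connective/adipose",
    "mucosa",
    "necrosis",
    "inflammation",
    "mucus",
)


@dataclass
class PipelineConfig:
    """All knobs of the cartography pipeline and its endpoints.

    Unknown keys are rejected on load; the full config is serialized into
    every run's output directory so a run can be reproduced from its
    manifest alone.
    """

    white_threshold: float = DEFAULT_WHITE_THRESHOLD
    analysis_downsample: int = 16
    stain_matrix: str | list = "he"          # "he", "h-dab", or a 3x3 row list
    superpixels: SuperpixelConfig = field(default_factory=SuperpixelConfig)
    patch_size: int = 224
    patch_limit: int = 10
    coverage_threshold: float = 0.5
    seed: int = 0
    class_names: tuple = DEFAULT_CLASS_NAMES
    rejection_threshold: float = 0.1
    closing_radius: int = 10
    opening_radius: int = 5
    margin_width_um: float = 500.0

    def __post_init__(self) -> None:
        if self.patch_size % self.analysis_downsample != 0:
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by "
                f"analysis_downsample {self.analysis_downsample}"
            )
        if not 0.0 < self.coverage_threshold <= 1.0:
            raise ValueError("coverage_threshold must be in (0, 1]")
        if not 0.0 <= self.rejection_threshold <= 1.0:
            raise ValueError("rejection_threshold must be in [0, 1]")
        if len(self.class_names) < 2:
            raise ValueError("need at least two class names")
        self.class_names = tuple(self.class_names)
        if isinstance(self.superpixels, dict):
            self.superpixels = SuperpixelConfig(**self.superpixels)

    def resolve_stain_matrix(self) -> stain.StainMatrix:
        if isinstance(self.stain_matrix, str):
            key = self.stain_matrix.lower().replace("_", "-")
            if key == "he":
                return stain.StainMatrix.he()
            if key == "h-dab":
                return stain.StainMatrix.h_dab()
            raise ValueError(f"unknown stain matrix preset {self.stain_matrix!r}")
        arr = np.asarray(self.stain_matrix, dtype=float)
        if arr.shape != (3, 3):
            raise ValueError("stain_matrix must be 'he', 'h-dab', or a 3x3 array")
        return stain.StainMatrix.from_rows(list(arr), ["S1", "S2", "S3"])

    # -- (de)serialization -------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        data = asdict(self)
        data["class_names"] = list(self.class_names)
        if isinstance(data["stain_matrix"], np.ndarray):
            data["stain_matrix"] = data["stain_matrix"].tolist()
        return data

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
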