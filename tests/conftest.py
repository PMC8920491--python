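"""Shared fixtures: small phantoms and toy-raster loaders."""

from pathlib import Path

import numpy as np
import pytest

from slidecarto.config import DEFAULT_CLASS_NAMES, PipelineConfig
from slidecarto.synthetic import PhantomSpec, make_phantom

DATA_DIR = Path(__file__).parent / "data"


def load_toy(name: str) -> np.ndarray:
    """Read a digit-grid text fixture into a uint8 raster."""
    lines = (DATA_DIR / name).read_text().splitlines()
    return np.array([[int(ch) for ch in line] for line in lines if line], dtype=np.uint8)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-scale phantom: 96x96 analysis plane (1536x1536 native)."""
    return PhantomSpec(analysis_shape=(96, 96), region_scale_px=30, margin_px=6, n_fissures=1, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec)


@pytest.fixture
def small_config(small_spec) -> PipelineConfig:
    return PipelineConfig(seed=7, class_names=small_spec.class_names)


@pytest.fixture
def class_names():
    return DEFAULT_CLASS_NAMES
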