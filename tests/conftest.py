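import numpy as np
import pytest

from fixmap.geometry import AOI_LABELS, AoiRect, FaceGeometry, Rect
from fixmap.synth import CANONICAL_BOUNDS, CANONICAL_LAYOUT, GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def canonical_face() -> FaceGeometry:
    """One face with the canonical (unjittered) AOI layout."""
    aois = {
        lab: AoiRect(*rect, label=lab) for lab, rect in CANONICAL_LAYOUT.items()
    }
    return FaceGeometry("face000", aois, CANONICAL_BOUNDS, "upright")


@pytest.fixture
def small_config() -> GeneratorConfig:
    """A fast, deliberately small synthetic experiment."""
    return GeneratorConfig(
        n_participants=3,
        n_faces=4,
        trials_per_cell_study=2,
        trials_per_cell_test=2,
        seed=7,
    )
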