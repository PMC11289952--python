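import numpy as np
import pytest

from chromascape.images import ConeCatchImage
from chromascape.visual_model import VisualSystem, clustered_from_class_map


@pytest.fixture(scope="session")
def vs() -> VisualSystem:
    return VisualSystem()


# two colors whose achromatic contrast is exactly 4 dS for the default
# observer (dbl ratio e^(4 * 0.05)) and whose chromatic contrast is zero
TWO_LUM_COLORS = np.array(
    [
        [0.5, 0.5, 0.5, 0.5],
        [0.5, 0.5, 0.5, 0.5 * np.exp(0.2)],
    ]
)


@pytest.fixture(scope="session")
def lum_pair_colors() -> np.ndarray:
    return TWO_LUM_COLORS.copy()


def make_image(data: np.ndarray, px_per_mm: float = 1.0) -> ConeCatchImage:
    return ConeCatchImage(np.asarray(data, dtype=np.float64), px_per_mm)


@pytest.fixture
def checkerboard(vs):
    """4x4 two-class checkerboard with dL = 4 exactly between classes."""
    cm = np.indices((4, 4)).sum(axis=0) % 2
    return clustered_from_class_map(cm, TWO_LUM_COLORS, 1.0, vs)


@pytest.fixture
def uniform_clustered(vs):
    cm = np.zeros((4, 4), dtype=int)
    return clustered_from_class_map(cm, TWO_LUM_COLORS, 1.0, vs)
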