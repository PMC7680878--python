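import numpy as np
import pytest

from flocia import SyntheticFlowerSpec, default_palette, generate_flower

MIX_COMPOSITION = {"medium yellow": 0.6, "orange": 0.3, "reddish brown": 0.1}


@pytest.fixture(scope="session")
def palette():
    return default_palette()


@pytest.fixture(scope="session")
def mix_flower():
    """A three-color flower (60/30/10) with ground truth, fixed seed."""
    spec = SyntheticFlowerSpec(seed=7, composition=dict(MIX_COMPOSITION))
    img, truth = generate_flower(spec)
    return spec, img, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0
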