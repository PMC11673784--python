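import numpy as np
import pytest

from milsurv.preprocess import StainProfile


@pytest.fixture()
def he_matrix() -> np.ndarray:
    """A known hematoxylin/eosin OD basis with unit columns."""
    S = np.array([[0.65, 0.07],
                  [0.70, 0.99],
                  [0.29, 0.11]])
    return S / np.linalg.norm(S, axis=0, keepdims=True)


@pytest.fixture()
def he_profile(he_matrix) -> StainProfile:
    return StainProfile(he_matrix, np.array([1.5, 1.2]))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
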