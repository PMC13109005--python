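import numpy as np
import pytest

from multistudyfa import MultiStudyDataset


def make_dataset(seed: int = 0, S: int = 2, n: int = 40, P: int = 6,
                 k: int = 2) -> tuple[MultiStudyDataset, np.ndarray]:
    """Small shared-factor dataset with known loadings (for smoke tests)."""
    rng = np.random.default_rng(seed)
    phi = rng.normal(size=(P, k))
    studies = []
    for _ in range(S):
        F = rng.normal(size=(n, k))
        studies.append(F @ phi.T + 0.3 * rng.normal(size=(n, P)))
    return MultiStudyDataset(studies), phi


@pytest.fixture
def small_data():
    data, phi = make_dataset(seed=11)
    return data, phi
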