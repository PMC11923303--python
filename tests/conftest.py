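import numpy as np
import pytest

from tilscore.stainnorm import REFERENCE_STAIN_MATRIX, default_target_profile
from tilscore.synthgen import PatchSpec, generate_patch


def angular_error_deg(v: np.ndarray, w: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip(v @ w, -1.0, 1.0))))


@pytest.fixture(scope="session")
def reference_matrix() -> np.ndarray:
    return REFERENCE_STAIN_MATRIX


@pytest.fixture(scope="session")
def target_profile():
    return default_target_profile()


@pytest.fixture(scope="session")
def tissue_patch():
    """A standard noiseless tissue patch: 3 lymphocytes + 1 tumor cell."""
    patch, cells, label = generate_patch(
        PatchSpec(n_lymphocytes=3, n_tumor_cells=1, noise_sd=0.0, seed=11)
    )
    return patch, cells, label
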