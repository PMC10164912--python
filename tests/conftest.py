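import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glycopssm.alphabet import MATRIX_AA, MATRIX_AA_INDEX
from glycopssm.scoring import ScoringMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_single_residue_matrix(
    length: int = 5, residue: str = "A", value: float = 1.0
) -> ScoringMatrix:
    """Matrix scoring `value` for one residue at every offset, 0 elsewhere."""
    values = np.zeros((len(MATRIX_AA), length - 1))
    values[MATRIX_AA_INDEX[residue], :] = value
    return ScoringMatrix(length, values, name=f"{residue}-only")


@pytest.fixture
def a_matrix() -> ScoringMatrix:
    """L=5 matrix worth 1.0 per flanking alanine."""
    return make_single_residue_matrix()


@pytest.fixture
def random_matrix() -> ScoringMatrix:
    rng = np.random.default_rng(42)
    return ScoringMatrix(
        39, rng.normal(size=(len(MATRIX_AA), 38)), name="random"
    )
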