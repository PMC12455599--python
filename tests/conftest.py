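import numpy as np
import pytest

from space_st.datatypes import ExpressionMatrix, SpatialCoords
from space_st.kernels import make_kernel_bank
from space_st.simulate import _jittered_grid


@pytest.fixture(scope="session")
def small_coords() -> SpatialCoords:
    """60 spots on a jittered grid in the unit square."""
    rng = np.random.default_rng(11)
    return SpatialCoords(_jittered_grid(60, rng))


@pytest.fixture(scope="session")
def medium_coords() -> SpatialCoords:
    """200 spots, enough for asymptotically calibrated p-values."""
    rng = np.random.default_rng(12)
    return SpatialCoords(_jittered_grid(200, rng))


@pytest.fixture(scope="session")
def medium_bank(medium_coords):
    return make_kernel_bank(medium_coords)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def expression_from(values: np.ndarray, spot_ids, normalized=True) -> ExpressionMatrix:
    return ExpressionMatrix(
        values,
        [f"g{i + 1}" for i in range(values.shape[0])],
        list(spot_ids),
        normalized,
    )
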