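import numpy as np
import pytest

from betahelix import (
    EXAMPLE_RUNG_SEQUENCE,
    GeometryParams,
    RungLayout,
    build_helix,
    build_trimer,
)

CONTROL_PEPTIDE = "QIAALEQEIAALEQEIAALQ"


@pytest.fixture(scope="session")
def layout() -> RungLayout:
    return RungLayout(EXAMPLE_RUNG_SEQUENCE)


@pytest.fixture(scope="session")
def params() -> GeometryParams:
    return GeometryParams()


@pytest.fixture(scope="session")
def helix7(layout, params):
    return build_helix(layout, params, 7)


@pytest.fixture(scope="session")
def trimer7(layout, params):
    return build_trimer(layout, params, 7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation and a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.normal(scale=5.0, size=3)
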