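import numpy as np
import pytest

from milekin import MilestoningModel, PotentialSpec, build_radial_model

# the 22 concentric milestone radii of the larger kinase layout (angstrom)
RADII_22 = [
    2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0, 8.5,
    9.0, 9.5, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0,
]


@pytest.fixture(scope="session")
def kinase_model() -> MilestoningModel:
    return build_radial_model(RADII_22)


@pytest.fixture(scope="session")
def uniform_model() -> MilestoningModel:
    """10 uniformly spaced milestones at 1..10."""
    return build_radial_model(np.arange(1.0, 11.0))


@pytest.fixture(scope="session")
def offset_model() -> MilestoningModel:
    """Half-spacing innermost milestone: 0.5, 1.5, ..., 9.5."""
    return build_radial_model(np.arange(0.5, 10.0))


@pytest.fixture(scope="session")
def flat() -> PotentialSpec:
    return PotentialSpec(kind="flat")


def tridiagonal_generator(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random birth-death generator with positive nearest-neighbour rates."""
    q = np.zeros((n, n))
    for i in range(n - 1):
        q[i, i + 1] = rng.uniform(0.5, 2.0)
    for i in range(1, n):
        q[i, i - 1] = rng.uniform(0.5, 2.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q
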