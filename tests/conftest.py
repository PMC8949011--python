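"""Shared fixtures for the structphy test suite."""

import numpy as np
import pytest

from structphy.simdata import generate_backbone
from structphy.structio import Structure


@pytest.fixture(scope="session")
def backbone60():
    return generate_backbone(60, seed=7)


@pytest.fixture(scope="session")
def backbone120():
    return generate_backbone(120, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_structure(coords, id="s", sequence=None, **kwargs) -> Structure:
    coords = np.asarray(coords, dtype=float)
    if sequence is None:
        sequence = "A" * len(coords)
    return Structure(id=id, sequence=sequence, coords=coords, **kwargs)


def random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def rigid_copy(s: Structure, rng, id=None) -> Structure:
    R = random_rotation(rng)
    t = rng.uniform(-50, 50, size=3)
    return Structure(
        id=id or s.id + "_rt",
        sequence=s.sequence,
        coords=s.coords @ R.T + t,
        resnums=s.resnums.copy(),
    )
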