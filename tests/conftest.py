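import numpy as np
import pytest

from aftm import Config, MembranePlacement
from aftm.fixtures import make_helix_bundle, make_placement, make_reentrant_hairpin


@pytest.fixture
def cfg():
    return Config()


@pytest.fixture
def bundle4():
    """4-helix bundle: (model, truth segments, planar geometry)."""
    return make_helix_bundle(4, seed=11)


@pytest.fixture
def bundle4_placement(bundle4):
    model, truth, geometry = bundle4
    return make_placement(model, truth, geometry, seed=11)


@pytest.fixture
def hairpin_placement():
    model, seg, geometry = make_reentrant_hairpin(seed=7)
    return MembranePlacement(structure=model, geometry=geometry, raw_segments=(seg,)), seg


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
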