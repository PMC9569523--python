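import numpy as np
import pytest
from hypothesis import settings

import phosbench as pb
from phosbench.synthetic_data import STATE_ANGLES

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def helix12() -> pb.Conformation:
    """Ideal 12-residue alpha helix at (phi, psi) = (-57, -47)."""
    return pb.build_backbone("A" * 12, [STATE_ANGLES["H"]] * 12)


@pytest.fixture(scope="session")
def strand12() -> pb.Conformation:
    """Ideal 12-residue extended strand with no partner."""
    return pb.build_backbone("A" * 12, [STATE_ANGLES["E"]] * 12)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation from a QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
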