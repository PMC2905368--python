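import numpy as np
import pytest

from zfdock.datasets import ZIF268_SEQUENCE, protein_chain_from_sequence
from zfdock.fixtures import DecoyConfig, make_wrapped_complex
from zfdock.structures import annotate_zinc_fingers


@pytest.fixture(scope="session")
def wrapped():
    """Default wrapped pseudo-complex with ground truth (expensive; shared)."""
    return make_wrapped_complex(DecoyConfig())


@pytest.fixture(scope="session")
def wrapped_structure(wrapped):
    return wrapped[0]


@pytest.fixture(scope="session")
def wrapped_truth(wrapped):
    return wrapped[1]


@pytest.fixture(scope="session")
def zif268_domains():
    chain = protein_chain_from_sequence(ZIF268_SEQUENCE)
    return annotate_zinc_fingers(chain)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation matrix (QR-based)."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
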