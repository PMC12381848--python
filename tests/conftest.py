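import numpy as np
import pytest

from confscape.ensembles import ConformationEnsemble, pool
from confscape.synthetic import PolymerSpec, generate_polymer_ensemble


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ensembles():
    """Three labeled 26-residue ensembles, 40 frames each."""
    specs = {
        "coil": PolymerSpec(26, compactness=0.2, seed=1),
        "globule": PolymerSpec(26, compactness=0.7, seed=2),
        "hairpin": PolymerSpec(
            26, compactness=0.5, exclusive_motif=((2, 20, 8.0),), seed=3
        ),
    }
    return [generate_polymer_ensemble(s, 40, label=k) for k, s in specs.items()]


@pytest.fixture(scope="session")
def small_pooled(small_ensembles):
    return pool(small_ensembles)


@pytest.fixture(scope="session")
def random_conformations(rng):
    """60 random 10-residue conformations (unit-free coordinates, Å scale)."""
    return rng.normal(scale=5.0, size=(60, 10, 3))


def random_rotation(rng):
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
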