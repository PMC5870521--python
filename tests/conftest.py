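import numpy as np
import pytest

from phylomorph.geometry import LandmarkConfiguration, SymmetryMap
from phylomorph.simulate import SimulationSpec, default_symmetry_map, default_template


@pytest.fixture(scope="session")
def template() -> np.ndarray:
    return default_template()


@pytest.fixture(scope="session")
def symmetry() -> SymmetryMap:
    return default_symmetry_map()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


def random_config(rng, k=17, scale=30.0, specimen_id="s"):
    return LandmarkConfiguration(
        specimen_id=specimen_id, coords=rng.normal(0.0, scale, (k, 3))
    )


def random_rotation(rng) -> np.ndarray:
    """Uniform proper rotation from the QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def small_bundle():
    """Small complete synthetic study: tree, means, specimens, metadata."""
    from phylomorph.simulate import simulate_dataset

    spec = SimulationSpec(
        n_tips=8, n_specimens_per_species=3, seed=42, missing_rate=0.0
    )
    tree, means, configs, meta = simulate_dataset(spec)
    return spec, tree, means, configs, meta
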