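import numpy as np
import pytest

from fabkit.structure_io import apply_domain_map
from fabkit.synth_fixtures import ToyFabSpec, make_toy_fab


@pytest.fixture(scope="session")
def static_fab():
    """Single-frame unperturbed toy Fab with its map and ground truth."""
    structure, dmap, truth = make_toy_fab(ToyFabSpec(n_frames=1, seed=11))
    return apply_domain_map(structure, dmap), truth


@pytest.fixture(scope="session")
def small_fv():
    """Small Fv-only trajectory with jitter, for ensemble statistics."""
    structure, dmap, truth = make_toy_fab(
        ToyFabSpec(n_frames=20, seed=5, fv_only=True, jitter_sigma=0.15)
    )
    return apply_domain_map(structure, dmap), truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
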