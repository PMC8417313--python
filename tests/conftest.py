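import numpy as np
import pytest

from vesselfuse import VesselTreeSpec, generate_tree, render_fundus, straight_tube


@pytest.fixture(scope="session")
def tree_sample():
    """One mid-sized rendered vascular tree shared across read-only tests."""
    sample = generate_tree(VesselTreeSpec(image_size=96, seed=11))
    return render_fundus(sample, seed=12)


@pytest.fixture(scope="session")
def small_trees():
    """Ten small seeded trees for property checks over varied geometry."""
    return [generate_tree(VesselTreeSpec(image_size=64, n_roots=2, seed=s))
            for s in range(10)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tube():
    return straight_tube(48, 5.0)
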