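import numpy as np
import pytest

from comboloc import NucleusModel, generate_nucleus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_nucleus():
    """One quickly generated nucleus with few clusters, plus ground truth."""
    model = NucleusModel(n_clusters=25, nucleus_radius_nm=3000.0, seed=7)
    points, truth = generate_nucleus(model)
    return points, truth
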