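import numpy as np
import pytest

from trajfuse.datasets import generate_spiral, generate_study
from trajfuse.datasets.spiral import SpiralParams
from trajfuse.features import ScatterConfig
from trajfuse.prep import PrepConfig


@pytest.fixture(scope="session")
def spiral():
    """Default spiral: 120 labeled, 300 unlabeled."""
    return generate_spiral(120, 300, seed=0)


@pytest.fixture(scope="session")
def noiseless_spiral():
    return generate_spiral(120, 300, SpiralParams(noise_sd=0.0), seed=0)


@pytest.fixture(scope="session")
def small_study():
    """Reduced study for unit tests: 64-px images, one live movie and two
    fixed datasets with disjoint channel pairs."""
    return generate_study(
        16, [(8, ("dpERK", "Twi")), (8, ("Dl", "rho"))],
        image_size=64, noise_sd=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def small_cfgs():
    return dict(prep_cfg=PrepConfig(canonical_size=64),
                scatter_cfg=ScatterConfig(averaging_scale=32))


def random_connected_graph(rng, n, n_labeled, p_cols=1):
    """Random symmetric affinity with guaranteed connectivity, plus labels."""
    W = rng.uniform(0.0, 1.0, (n, n))
    W = 0.5 * (W + W.T)
    W[W < 0.45] = 0.0          # sparsify but stay connected via the chain below
    for i in range(n - 1):
        W[i, i + 1] = W[i + 1, i] = max(W[i, i + 1], 0.5)
    np.fill_diagonal(W, 1.0)
    lab = rng.choice(n, size=n_labeled, replace=False)
    Y = rng.normal(size=(n_labeled, p_cols)) if p_cols > 1 else rng.normal(size=n_labeled)
    return W, lab, Y
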