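import numpy as np
import pytest

from robustcounts import DesignResponse, gen_covariate
from robustcounts.simulate import sample_family


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_sim_data(family, beta0, beta1, n=200, seed=0):
    """One simulated dataset on the balanced binary design."""
    rng = np.random.default_rng(seed)
    x = gen_covariate(n)
    mu = np.exp(beta0 + beta1 * x)
    y = sample_family(family, mu, rng)
    X = np.column_stack([np.ones(n), x])
    return DesignResponse(y, X), x
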