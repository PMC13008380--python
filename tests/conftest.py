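import numpy as np
import pytest

import couplingbench as cb
from couplingbench.types import ParcellatedTimeSeries


@pytest.fixture(scope="session")
def small_network():
    return cb.make_true_network(n_regions=8, edge_density=0.25, rng_seed=11)


@pytest.fixture(scope="session")
def subject_series(small_network):
    return cb.simulate_subject_series(
        small_network, n_frames=600, tr_s=0.72, rng_seed=12, noise_sd=0.3
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def gaussian_series(n_frames, corr, rng, tr_s=1.0, subject_id="sub-g"):
    """I.i.d. multivariate Gaussian series with the given correlation."""
    corr = np.asarray(corr, dtype=float)
    chol = np.linalg.cholesky(corr)
    data = rng.standard_normal((n_frames, corr.shape[0])) @ chol.T
    return ParcellatedTimeSeries(subject_id, data, tr_s)
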