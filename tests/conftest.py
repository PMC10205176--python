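import logging

import numpy as np
import pandas as pd
import pytest

import petquant as pq

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def schedule():
    return pq.make_frame_schedule()


@pytest.fixture(scope="session")
def ref_tac(schedule):
    return pq.simulate_reference_tac(schedule, amplitude=30.0)


@pytest.fixture(scope="session")
def small_config():
    """Small phantom grid for fast per-test subjects."""
    return pq.PhantomConfig(grid_shape=(16, 16, 8))


@pytest.fixture(scope="session")
def noiseless_subject(small_config):
    return pq.generate_subject(small_config.noiseless(), "HC", seed=7)


@pytest.fixture(scope="session")
def noiseless_basis(noiseless_subject, small_config):
    return pq.make_class_basis(noiseless_subject.dynamic_image.schedule,
                               small_config.noiseless())


def gaussian_table(n_per_class=(10, 10), n_features=4, shift=0.0, seed=0,
                   names=None):
    """Two-cluster feature table; the first feature carries the group shift."""
    rng = np.random.default_rng(seed)
    n_ad, n_hc = n_per_class
    names = names or [f"f{i}" for i in range(n_features)]
    x = rng.standard_normal((n_ad + n_hc, n_features))
    x[:n_ad, 0] += shift
    labels = ["AD"] * n_ad + ["HC"] * n_hc
    ids = [f"s{i:02d}" for i in range(n_ad + n_hc)]
    return pq.FeatureTable(ids, labels, pd.DataFrame(x, columns=names))
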