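"""Shared fixtures: small seeded cohorts and fitted models reused across tests."""

import numpy as np
import pytest

from spherepace import rfpca, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sample():
    """Sparse single-group cohort, small enough for fast unit tests."""
    params = simulate.single_group_scenario(120, seed=101)
    sample, truth = simulate.generate_sample(params)
    return sample, truth


@pytest.fixture(scope="session")
def small_fit(small_sample):
    """One fitted model shared by tests that only read it."""
    sample, truth = small_sample
    fitted = rfpca.fit_rfpca(sample, rfpca.RFPCAOptions(cov_bw_factor=2.5))
    return fitted, sample, truth


@pytest.fixture(scope="session")
def two_group_sample():
    params = simulate.default_scenario(seed=202, n_subjects=(60, 60))
    sample, truth = simulate.generate_sample(params)
    return sample, truth
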