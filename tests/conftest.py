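import numpy as np
import pytest

from ctglab.synthetic import SimParams, simulate_cohort, simulate_record


@pytest.fixture(scope="session")
def small_cohort():
    """A modest labelled cohort shared across tests (fixed seed)."""
    params = SimParams(n_cases=300, seed=2024)
    dataset, truths, _ = simulate_cohort(params)
    return params, dataset, truths


@pytest.fixture(scope="session")
def one_record():
    params = SimParams(seed=5)
    record, truth = simulate_record(params, case_seed=555, case_id="fix")
    return params, record, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
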