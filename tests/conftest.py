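import numpy as np
import pytest

from nocitoj import ParameterGrid, build_exp1_config, build_exp2_config
from nocitoj.observers import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_grid():
    return ParameterGrid.default()


@pytest.fixture(scope="session")
def exp1_config():
    return build_exp1_config()


@pytest.fixture(scope="session")
def exp2_config():
    return build_exp2_config()


@pytest.fixture(scope="session")
def small_grid():
    """3x3 grid for exhaustive-enumeration tests."""
    return ParameterGrid(
        alpha_values=np.array([-50.0, 0.0, 50.0]),
        beta_values=np.array([0.01, 0.05, 0.25]),
        prior=np.full((3, 3), 1 / 9),
    )


@pytest.fixture(scope="session")
def tiny_exp1_logs(exp1_config):
    """Four simulated participants with a strong, precise effect; used for
    pipeline structure tests (fast, deterministic)."""
    cohort = CohortSpec(
        n=4,
        cell_shift_means={("near",): 12.0, ("far",): 6.0},
        cell_shift_sds={("near",): 2.0, ("far",): 2.0},
        beta_mean=0.08,
        log_beta_sd=0.1,
        lapse=0.0,
    )
    return simulate_cohort(cohort, exp1_config, seed=424242)


def brute_force_select(state):
    """Independent expected-entropy minimizer: exhaustive loops over every
    (SOA, response, grid point) triple, straight from the definition."""
    post = state.posterior.reshape(-1)
    n_soa = state.soa_set.size
    cache = state.likelihood_cache.reshape(n_soa, -1)
    expected = np.empty(n_soa)
    for s in range(n_soa):
        eh = 0.0
        for r in (0, 1):
            like = cache[s] if r == 1 else 1.0 - cache[s]
            p_r = float(np.sum(like * post))
            if p_r == 0.0:
                continue
            upd = like * post / p_r
            h = -sum(q * np.log(q) for q in upd if q > 0)
            eh += p_r * h
        expected[s] = eh
    best = expected.min()
    cands = state.soa_set[expected <= best + 1e-12]
    cands = cands[np.abs(cands) <= np.abs(cands).min() + 1e-12]
    return float(cands.min()), expected
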