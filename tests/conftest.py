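import numpy as np
import pytest

from arthrocomp import prep, propensity, registry
from arthrocomp.config import SimConfig


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(n_procedures=20000, seed=11)


@pytest.fixture(scope="session")
def cohort_20k(default_config):
    return registry.generate_cohort(default_config)


@pytest.fixture(scope="session")
def analysis_20k(cohort_20k):
    eligible, _ = prep.apply_eligibility(cohort_20k)
    analysis, _ = prep.complete_case_filter(eligible)
    return analysis


@pytest.fixture(scope="session")
def ps_20k(analysis_20k):
    return propensity.fit_propensity(analysis_20k)


@pytest.fixture(scope="session")
def matched_20k(analysis_20k, ps_20k):
    return propensity.match_one_to_one(analysis_20k, ps_20k, seed=7)


@pytest.fixture(scope="session")
def weighted_20k(analysis_20k, ps_20k):
    return propensity.iptw_weights(analysis_20k, ps_20k)


@pytest.fixture(scope="session")
def matched_pop_20k(analysis_20k, matched_20k):
    return matched_20k.population(analysis_20k)


def simulate_two_arm_exponential(n, hr, rate0=0.3, censor=3.0, seed=0):
    """Simple PH two-arm exponential dataset (times, events, arm)."""
    rng = np.random.default_rng(seed)
    arm = (np.arange(n) % 2).astype(float)
    rate = rate0 * np.where(arm == 1, hr, 1.0)
    t = rng.exponential(1.0 / rate, n)
    obs = np.minimum(t, censor)
    d = (t <= censor).astype(float)
    return obs, d, arm
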