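import time

import pytest

from cbci.fusion import VoteMatrices
from cbci.simulate import end_to_end_fixture, simulate_population
from cbci.workflow import analyse_population, compute_confidence_table

# Seeds of the reference simulated experiment used throughout the suite.
TRIAL_SEED = 0
BEHAVIOUR_SEED = 1


@pytest.fixture(scope="session")
def mini_population():
    """4 observers x 56 trials, with epochs: fast pipeline fixture."""
    return end_to_end_fixture(seed=7)


@pytest.fixture(scope="session")
def default_population():
    """The full default study: 10 observers x 224 trials with EEG."""
    return simulate_population(trial_seed=TRIAL_SEED, behaviour_seed=BEHAVIOUR_SEED)


@pytest.fixture(scope="session")
def default_votes(default_population):
    """Out-of-fold nf and decision weights for the default study (k=16)."""
    t0 = time.perf_counter()
    votes = compute_confidence_table(default_population)
    votes.attrs["elapsed_s"] = time.perf_counter() - t0
    return votes


@pytest.fixture(scope="session")
def default_matrices(default_votes):
    return VoteMatrices.from_table(default_votes)


@pytest.fixture(scope="session")
def default_results(default_population, default_votes):
    """Complete analysis (group tables + ERP contrast) with its wall time."""
    t0 = time.perf_counter()
    results = analyse_population(default_population, votes=default_votes)
    results.elapsed_s = time.perf_counter() - t0
    return results
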