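import pytest
from hypothesis import HealthCheck, settings

from stratseq import default_scheme, exact_marginal_cohort, run_trials, table1_spec

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Master seed for all session-level stochastic fixtures; fixed up front.
MASTER_SEED = 1234


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def table1_batch():
    """5000-patient cohort whose marginal counts match the reference table exactly."""
    return exact_marginal_cohort(table1_spec(), seed=MASTER_SEED)


@pytest.fixture(scope="session")
def stratified_ensemble_2000(table1_batch, scheme):
    """2000 independent stratified re-splits of the reference cohort."""
    return run_trials(table1_batch, scheme, "stratified", 2000, master_seed=MASTER_SEED)
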