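import pytest

from chunkspan.cohort import DEFAULT_COHORT, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort_logs():
    """One default-sized synthetic cohort shared across statistical tests."""
    return simulate_cohort(DEFAULT_COHORT, rng_seed=101)


@pytest.fixture(scope="session")
def small_cohort_logs():
    """A small cohort for structural (non-statistical) checks."""
    import dataclasses

    hyper = dataclasses.replace(DEFAULT_COHORT, n_participants=8)
    return simulate_cohort(hyper, rng_seed=7)
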