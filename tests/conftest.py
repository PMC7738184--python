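import dataclasses

import pytest

from chromadapt import (
    CohortParams,
    ObserverParams,
    analyze_cohort,
    default_monitor,
    gain_fundamentals,
    simulate_cohort,
    synth_red_glasses,
    task_fundamentals,
)


@pytest.fixture(scope="session")
def monitor():
    return default_monitor()


@pytest.fixture(scope="session")
def glasses():
    return synth_red_glasses()


@pytest.fixture(scope="session")
def task_fund():
    return task_fundamentals()


@pytest.fixture(scope="session")
def gain_fund():
    return gain_fundamentals()


def noise_free_cohort(n_observers: int = 3) -> CohortParams:
    """Cohort with zero between-observer SDs and zero match noise."""
    sds = {
        f.name: 0.0
        for f in dataclasses.fields(CohortParams)
        if f.name.startswith("sd_")
    }
    return CohortParams(
        n_observers=n_observers,
        means=ObserverParams(noise_sd=0.0, matches_per_block_mean=1.0),
        latent_loading=0.0,
        seed=0,
        **sds,
    )


@pytest.fixture(scope="session")
def noise_free_records():
    return simulate_cohort(noise_free_cohort())


@pytest.fixture(scope="session")
def default_records():
    """One default synthetic cohort (11 observers, full schedule)."""
    return simulate_cohort(CohortParams(seed=7))


@pytest.fixture(scope="session")
def default_report(default_records):
    return analyze_cohort(default_records)
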