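"""Shared fixtures: synthetic cohorts at the default study conditions and a
fast low-load configuration for tests that do not depend on mutation load."""

from __future__ import annotations

import pytest

from cjmel.simulate import CohortConfig, generate_cohort


def fast_config(**overrides) -> CohortConfig:
    """Small-load config for tests where absolute load does not matter."""
    defaults = dict(
        nonneutral_means={"tarsal": 30.0, "bulbar": 60.0},
        indel_mean=15.0,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def cohort():
    """One default cohort at the study conditions (14 samples)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def cohort_ensemble():
    """Six default cohorts for cohort-statistic checks (seeds 0-5)."""
    return [generate_cohort(CohortConfig(seed=s)) for s in range(6)]


@pytest.fixture()
def fast_cohort():
    return generate_cohort(fast_config(seed=5))
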