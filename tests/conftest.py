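"""Shared fixtures: small seeded cohorts and their derived datasets."""

from __future__ import annotations

import numpy as np
import pytest

from turnsignal import CohortConfig, build_datasets, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(
        n_healthy=4, n_mci=3,
        trips_per_participant=(2, 3),
        trip_duration_s=(90, 150),
        turn_count_per_trip=(3, 3),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_datasets(small_cohort):
    return build_datasets(small_cohort)


@pytest.fixture(scope="session")
def clean_trips(small_datasets):
    return small_datasets.trips


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
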