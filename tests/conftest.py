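"""Shared fixtures: one small synthetic study reused across test modules."""

import numpy as np
import pytest

from pollen_attrib import TruthParams, generate_bundle, compute_metrics
from pollen_attrib.climate_processing import annual_covariates, extract_station_series


@pytest.fixture(scope="session")
def small_truth() -> TruthParams:
    return TruthParams(seed=11, n_stations=12)


@pytest.fixture(scope="session")
def small_bundle(small_truth):
    return generate_bundle(small_truth, n_models=3)


@pytest.fixture(scope="session")
def small_metrics(small_bundle):
    metrics, exclusions = compute_metrics(small_bundle.pollen_records)
    return metrics


@pytest.fixture(scope="session")
def small_covariates(small_bundle):
    monthly = extract_station_series(small_bundle.observed_climate, small_bundle.stations)
    return annual_covariates(monthly, small_bundle.co2_series)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
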