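"""Shared fixtures: the default synthetic study sets and their heavy results.

Session-scoped so the expensive objects (379-sample datasets, MC-embedded
cross-validations) are computed once and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nmrmeat as nm

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: master seeds of the seeded study runs used throughout the suite
GEN_SEED = 1
CV_SEED = 2


@pytest.fixture(scope="session")
def raw_set() -> nm.SpectrumSet:
    return nm.simulate_dataset(nm.default_raw_config(seed=GEN_SEED), kind="raw")


@pytest.fixture(scope="session")
def raw_features(raw_set) -> nm.FeatureMatrix:
    return nm.preprocess_set(raw_set, nm.default_polar_spec())


@pytest.fixture(scope="session")
def raw_mccv(raw_features) -> nm.MCCVResult:
    return nm.run_mccv(raw_features, plan=nm.CVPlan(seed=CV_SEED))


@pytest.fixture(scope="session")
def processed_set() -> nm.SpectrumSet:
    return nm.simulate_dataset(nm.default_processed_config(seed=GEN_SEED), kind="processed")


@pytest.fixture(scope="session")
def processed_features(processed_set) -> nm.FeatureMatrix:
    return nm.preprocess_set(processed_set, nm.default_polar_spec())


@pytest.fixture(scope="session")
def processed_mccv(processed_features) -> nm.MCCVResult:
    return nm.run_mccv(processed_features, plan=nm.CVPlan(seed=CV_SEED))


@pytest.fixture(scope="session")
def nonpolar_set(raw_set) -> nm.SpectrumSet:
    return nm.simulate_paired_nonpolar_block(raw_set, nm.default_nonpolar_config(seed=GEN_SEED))


@pytest.fixture(scope="session")
def nonpolar_features(nonpolar_set) -> nm.FeatureMatrix:
    return nm.preprocess_set(nonpolar_set, nm.default_nonpolar_spec())


@pytest.fixture(scope="session")
def nonpolar_mccv(nonpolar_features) -> nm.MCCVResult:
    return nm.run_mccv(nonpolar_features, plan=nm.CVPlan(seed=CV_SEED))


@pytest.fixture(scope="session")
def fused_mccv(raw_features, nonpolar_features) -> nm.MCCVResult:
    return nm.run_fused_mccv(raw_features, nonpolar_features, plan=nm.CVPlan(seed=CV_SEED))


@pytest.fixture(scope="session")
def null_features() -> nm.FeatureMatrix:
    """Default raw-size dataset with all between-class differences removed."""
    lib, prof = nm.build_default_library()
    null_prof = nm.pooled_profiles(prof)
    sset = nm.simulate_dataset(
        nm.default_raw_config(seed=GEN_SEED), kind="raw", library=lib, profiles=null_prof
    )
    return nm.preprocess_set(sset, nm.default_polar_spec())


@pytest.fixture(scope="session")
def null_mccv(null_features) -> nm.MCCVResult:
    return nm.run_mccv(null_features, plan=nm.CVPlan(seed=CV_SEED))


@pytest.fixture(scope="session")
def carnosine_only_features() -> nm.FeatureMatrix:
    """Two classes (25 + 25) whose profiles differ in carnosine only."""
    lib, prof = nm.build_default_library()
    shared = dict(prof["lamb"].concentration_mean)
    high = dict(shared, carnosine=3.0)
    low = dict(shared, carnosine=1.0)
    cvs = dict(prof["lamb"].concentration_cv)
    profiles = {
        "pork": nm.SpeciesProfile("pork", high, dict(cvs)),
        "lamb": nm.SpeciesProfile("lamb", low, dict(cvs)),
    }
    cfg = nm.default_raw_config(seed=GEN_SEED + 7)
    cfg.n_per_class = {"pork": 25, "lamb": 25}
    sset = nm.simulate_dataset(cfg, kind="raw", library=lib, profiles=profiles)
    return nm.preprocess_set(sset, nm.default_polar_spec())


@pytest.fixture(scope="session")
def carnosine_peak_shifts() -> list[float]:
    lib, _ = nm.build_default_library()
    return lib.shifts("carnosine")
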