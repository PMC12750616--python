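"""Shared fixtures: small simulated cohorts reused across test modules."""

import pytest

from kinetrial.cohort_sim import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def clean_small_cohort():
    """Uncorrupted, uncalibrated 12-student cohort (fast, fully stochastic)."""
    return simulate_cohort(
        SimConfig(n_per_arm=6, seed=101, missing_rate=0.0, outlier_rate=0.0,
                  calibrate=False)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort: calibrated, with missingness and outliers."""
    return simulate_cohort(SimConfig(seed=42))
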