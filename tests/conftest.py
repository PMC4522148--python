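"""Shared fixtures: small simulated cohorts and derived tables."""

import pytest

from lohsel import calibration, landscape, simulate


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate cohort under the standard study conditions."""
    return simulate.generate_cohort(
        simulate.default_config(n_samples=40, n_loci=200, rng_seed=5)
    )


@pytest.fixture(scope="session")
def strong_cohort():
    """Cohort with strong planted effects in every model."""
    return simulate.generate_cohort(
        simulate.strong_config(n_samples=80, n_loci=400, rng_seed=9)
    )


@pytest.fixture(scope="session")
def strong_results(strong_cohort):
    return calibration.analyse_cohort(strong_cohort)


@pytest.fixture(scope="session")
def default_segments(default_cohort):
    return landscape.call_loh(default_cohort.acn)


@pytest.fixture(scope="session")
def thresholds():
    return landscape.ThresholdSet()
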