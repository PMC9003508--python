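"""Shared fixtures: the default synthetic cohort, generated once per session."""
import numpy as np
import pytest

from socspec import (
    SimConfig,
    average_sets,
    generate_cohort,
    generate_lab_measurements,
    generate_spectral_series,
    reflectance_to_absorbance,
    trim_and_resample,
)
from socspec.spectra import DEFAULT_KEEP
from socspec.synthetic import MIR, VNIR


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def cohort(sim_config):
    return generate_cohort(sim_config)


@pytest.fixture(scope="session")
def lab_table(cohort, sim_config):
    return generate_lab_measurements(cohort, sim_config)


@pytest.fixture(scope="session")
def spectral_series(cohort, sim_config):
    return generate_spectral_series(cohort, None, sim_config)


def preprocess(spectrum_set, domain):
    """Standard chain: absorbance, then trim/resample to the working grid."""
    return trim_and_resample(reflectance_to_absorbance(spectrum_set), *DEFAULT_KEEP[domain])


@pytest.fixture(scope="session")
def processed_series(spectral_series):
    """Absorbance series on the working grids, per domain."""
    return {
        domain: [preprocess(s, domain) for s in spectral_series.series[domain]]
        for domain in (VNIR, MIR)
    }


@pytest.fixture(scope="session")
def averaged_spectra(processed_series):
    """Across-series averaged absorbance spectra (the best-case inputs)."""
    return {domain: average_sets(sets) for domain, sets in processed_series.items()}


@pytest.fixture(scope="session")
def soc_true(cohort):
    return cohort.set_index("sample_id")["soc_true"]
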