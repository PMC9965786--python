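import numpy as np
import pytest

from flyage.age_models import ModelSettings
from flyage.chc import build_feature_table, filter_minor
from flyage.spectra import (average_replicates, preprocess_set,
                            spectra_to_feature_table)
from flyage.synthetic import (GeneratorParams, default_compound_catalog,
                              make_measurement_design, simulate_dataset)


@pytest.fixture(scope="session")
def catalog():
    return default_compound_catalog()


@pytest.fixture(scope="session")
def default_params():
    return GeneratorParams(seed=0)


@pytest.fixture(scope="session")
def noise_free_params():
    return GeneratorParams(seed=0, scatter_slope_sd=0.0, baseline_sd=0.0,
                           spectral_noise_sd=0.0, chc_noise_sd=0.0)


def _chc_table(temperature_C, params, filtered=True):
    design = make_measurement_design(temperature_C)
    _, profiles = simulate_dataset(design, params)
    if filtered:
        profiles = [filter_minor(p) for p in profiles]
    return build_feature_table(profiles, default_compound_catalog())


def _ftir_table(temperature_C, params):
    design = make_measurement_design(temperature_C)
    spectra, _ = simulate_dataset(design, params)
    processed = preprocess_set(spectra)
    per_rep = average_replicates(processed,
                                 ("temperature_C", "age_days", "replicate"))
    return spectra_to_feature_table(per_rep)


@pytest.fixture(scope="session")
def chc_table_30(default_params):
    """Default-noise CHC feature table at 30 C (24 samples x 37 compounds)."""
    return _chc_table(30, default_params)


@pytest.fixture(scope="session")
def ftir_table_30(default_params):
    return _ftir_table(30, default_params)


@pytest.fixture(scope="session")
def make_chc_table():
    return _chc_table


@pytest.fixture(scope="session")
def make_ftir_table():
    return _ftir_table


@pytest.fixture
def fast_settings():
    """Settings trimmed for test speed; permutations skipped separately."""
    return ModelSettings(n_perm=25, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
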