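import numpy as np
import pandas as pd
import pytest

from nirfat.deuterium import apply_qc
from nirfat.pipeline import compute_method_values
from nirfat.simulate import GeneratorConfig, generate_cohort
from nirfat.spectra import build_feature_matrix


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject cohort with spectra, shared across tests (read-only)."""
    return generate_cohort(GeneratorConfig(n_subjects=60, seed=11))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return build_feature_matrix(small_cohort.spectra)


@pytest.fixture(scope="session")
def small_methods(small_cohort):
    qc = apply_qc(small_cohort.cohort)
    return compute_method_values(small_cohort.cohort, qc)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def recovery_cohort():
    """n=300 cohort at default noise for parameter-recovery checks."""
    return generate_cohort(GeneratorConfig(n_subjects=300, seed=1))
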