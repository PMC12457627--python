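import numpy as np
import pytest

import hsibench as hb


@pytest.fixture(scope="session")
def spectral_model():
    return hb.SpectralModel()


@pytest.fixture(scope="session")
def small_cohort(spectral_model):
    """Six 32x32 patients on the full 100-band grid — shared unit-test cohort."""
    spec = hb.CohortSpec(n_patients=6, height=32, width=32, seed=5)
    return hb.generate_cohort(spec, spectral_model)


@pytest.fixture(scope="session")
def small_subset(small_cohort):
    return hb.sample_representative(small_cohort, fraction=0.02, seed=3)


@pytest.fixture(scope="session")
def grid100():
    return hb.WavelengthGrid.from_range(500.0, 995.0, 5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
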