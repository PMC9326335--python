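import numpy as np
import pytest

from tumorperf import optics, synthetic
from tumorperf.extinction import synthetic_extinction


@pytest.fixture(scope="session")
def ext():
    return synthetic_extinction()


@pytest.fixture(scope="session")
def surrogate():
    return optics.SurrogateModel()


@pytest.fixture(scope="session")
def wavelengths():
    return np.arange(450.0, 651.0, 2.0)


@pytest.fixture
def small_config():
    """A fast, fully populated cohort for pipeline-level tests."""
    return synthetic.CohortConfig(
        n_per_group={"CG": 3, "MET": 3, "MTD": 3},
        seed=11, missing_rate=0.0, artifact_rate=0.0,
        noise_sd_reflectance=0.0, subject_sd=0.0, spectra_per_visit=1,
        ct_noise_sd=0.0,
    )


@pytest.fixture
def clean_spectrum(ext, surrogate, wavelengths):
    """A noise-free calibrated spectrum with known generating parameters."""
    theta = optics.OpticalModelParams(thb=15.0, sto2=0.6, a=20.0, b=1.2)
    refl = optics.forward_reflectance(theta, wavelengths, ext, surrogate)
    return theta, optics.Spectrum(wavelengths, refl, {"raw_max": 30000.0})
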