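import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sempa import presets
from sempa.fitting import ForwardModel
from sempa.psd import lognormal_from_summary
from sempa.ri_model import HbFractions, ParticleComposition
from sempa.synthetic import default_species_optics

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def optics():
    """Deterministic fixture optics tables for all four species."""
    return default_species_optics()


@pytest.fixture(scope="session")
def dls_psd():
    return lognormal_from_summary(presets.DLS_SUMMARY)


@pytest.fixture(scope="session")
def base_composition():
    return ParticleComposition(
        presets.BETA_HB_HBMP, presets.BETA_GLHSA_HBMP, HbFractions(1.0, 0.0, 0.0)
    )


@pytest.fixture(scope="session")
def fit_wavelengths():
    return np.arange(300.0, 800.0 + 1e-9, 5.0)


@pytest.fixture(scope="session")
def fit_model(dls_psd, base_composition, optics, fit_wavelengths):
    """Shared cached forward model: grid-search spectra are memoised across
    every fitting test in the session."""
    return ForwardModel(dls_psd, base_composition, optics, fit_wavelengths)
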