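import numpy as np
import pytest

from ccn2pk import BolusScenario, InfusionScenario, SPRScenario
from ccn2pk.models import PlasmaCurve, TwoCompartmentMacro


@pytest.fixture
def textbook_macro() -> TwoCompartmentMacro:
    """A well-separated biexponential used across the compartmental tests."""
    return TwoCompartmentMacro(A=40.0, B=15.0, alpha=0.3, beta=0.03)


@pytest.fixture
def noise_free_bolus() -> BolusScenario:
    return BolusScenario(noise_cv=0.0, seed=11)


@pytest.fixture
def noisy_bolus() -> BolusScenario:
    return BolusScenario(seed=11)


@pytest.fixture
def noise_free_infusion() -> InfusionScenario:
    return InfusionScenario(noise_cv=0.0, seed=11)


@pytest.fixture
def noise_free_spr() -> SPRScenario:
    return SPRScenario(noise_sd=0.0, seed=11)


def make_curve(times, concs, censored=None, arm="control") -> PlasmaCurve:
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if censored is None:
        censored = np.zeros(len(times), dtype=bool)
    subjects = np.array([f"{arm}-{i}" for i in range(len(times))], dtype=object)
    return PlasmaCurve(subjects, times, concs, censored, arm=arm)
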