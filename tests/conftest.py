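import numpy as np
import pytest

from stnbeta.spectral import BetaParams, BroadbandParams, SpectralFit
from stnbeta.synthetic import gen_cohort


@pytest.fixture
def worked_broadband():
    # a=2, tau=10, c=1: B(10) = 1 + 2/e ≈ 1.7358
    return BroadbandParams(a=2.0, tau=10.0, c=1.0)


@pytest.fixture
def worked_beta():
    return BetaParams(A=3.0, f0=20.0, sigma=2.0)


@pytest.fixture
def worked_fit(worked_broadband, worked_beta):
    return SpectralFit(
        broadband=worked_broadband,
        beta=worked_beta,
        fit_range=(3.0, 45.0),
        r_squared=1.0,
        residuals=np.zeros(0),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (26 hemispheres), reused across tests."""
    return gen_cohort(seed=11)
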