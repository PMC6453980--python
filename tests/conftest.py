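import pytest

from mindread import (
    CognitiveParams,
    EnvironmentParams,
    IntensityModel,
    PayoffParams,
)


@pytest.fixture
def pay():
    return PayoffParams()  # b=1, d-=d+=5, c-=c+=3


@pytest.fixture
def fig_env():
    """Reference environment: t_bar=0.1, p=0.05, truncated-normal intensities."""
    return EnvironmentParams(
        lambda_e=9.0,
        lambda_d=1.0,
        p=0.05,
        intensity=IntensityModel("truncnorm", 0.5, 0.1),
    )


@pytest.fixture
def point_env():
    """Simplified case: every stimulus has intensity exactly 1."""
    return EnvironmentParams(
        lambda_e=1.0, lambda_d=1.0, p=0.25, intensity=IntensityModel("point", 1.0)
    )


@pytest.fixture
def cog_sigmoid():
    return CognitiveParams()  # u_B=0.3, rho_a=13.8155, rho_l=5, lambda_l=50


@pytest.fixture
def cog_step():
    """Step-linear activation with ramp fully inside [0, 1]."""
    return CognitiveParams(
        activation_kind="step_linear", rho_a=2.0, u_B=0.3, u_D=0.4625, lambda_l=5.0
    )
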