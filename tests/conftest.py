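import pytest
from hypothesis import HealthCheck, settings

from panelpower import (
    DesignOptions,
    GrossChangeSpecMeans,
    GrossChangeSpecProps,
    NetChangeSpecMeans,
    NetChangeSpecProps,
    TestParams,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ONE_SIDED = TestParams(alpha=0.05, power=0.80, sided="one")


@pytest.fixture
def means_net():
    """Net-change spec of the continuous worked design (delta=3, rho=0.9)."""
    return NetChangeSpecMeans(
        delta=3, sigma_x2=100, sigma_y2=75, rho=0.9, r=1.0, test=ONE_SIDED
    )


@pytest.fixture
def means_gross():
    """Gross-change spec of the continuous worked design (Delta=3, sigma_o2=200)."""
    return GrossChangeSpecMeans(delta_gross=3, sigma_o2=200, rho=0.9, test=ONE_SIDED)


@pytest.fixture
def props_net():
    return NetChangeSpecProps(p_t=0.5, p_t1=0.7, p_xy=0.45, r=1.0, test=ONE_SIDED)


@pytest.fixture
def props_gross():
    return GrossChangeSpecProps(p_t=0.5, p_t1=0.8, p_xy=0.45, test=ONE_SIDED)


@pytest.fixture
def default_options():
    return DesignOptions(theta=0.5, deff=1.0)
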