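import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

RT_OVER_F = 25.97  # mV; thermal voltage used for the reference conditions


@pytest.fixture(scope="session")
def kcl_bath():
    from bilayerlab import solutions

    return solutions.kcl_gradient(rt_over_f=RT_OVER_F)


@pytest.fixture(scope="session")
def ca_bath():
    from bilayerlab import solutions

    return solutions.cacl2_gradient(rt_over_f=RT_OVER_F)


@pytest.fixture(scope="session")
def mixture_bath():
    from bilayerlab import solutions

    return solutions.k_ca_mixture(rt_over_f=RT_OVER_F)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
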