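import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gsm2.core import InitialCondition, KineticRates

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Benchmark kinetics: r=4, a=0.1, count-scale pairwise rate 0.01,
# x0=100 sublethal / 0 lethal lesions, system size K = x0.
BENCH = dict(r=4.0, a=0.1, b_tilde=0.01)
LAM = BENCH["r"] + BENCH["a"]


@pytest.fixture(scope="session")
def rates_conc() -> KineticRates:
    """Benchmark rates on the concentration-scale convention (K = x0 = 100)."""
    return KineticRates(**BENCH, K=100.0)


@pytest.fixture(scope="session")
def rates_count() -> KineticRates:
    """Benchmark rates on the count scale (K = 1, so b = b_tilde)."""
    return KineticRates(**BENCH, K=1.0)


@pytest.fixture(scope="session")
def init100() -> InitialCondition:
    return InitialCondition(x0=100, y0=0)


@pytest.fixture(scope="session")
def macro_conc(rates_conc):
    """Concentration-scale macroscopic solution over the benchmark horizon."""
    from gsm2.macroscopic import solve_mkm
    return solve_mkm(rates_conc, 1.0, 0.0, np.linspace(0.0, 10.0, 2001))


@pytest.fixture(scope="session")
def moments_conc(rates_conc, macro_conc):
    from gsm2.lna import solve_covariances
    return solve_covariances(rates_conc, macro_conc)
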