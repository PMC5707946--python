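import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from greycast import GM11, three_gorges_series

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tg():
    """Packaged Three Gorges wastewater series, keyed by label."""
    return three_gorges_series()


@pytest.fixture(scope="session")
def tg_results(tg):
    """Optimized-initial GM(1,1) fits of the four modelled series."""
    return {lab: GM11(tg[lab]).fit(init="optimized") for lab in ("W1", "W2", "W3", "W4")}


def random_model_series(rng, n=7):
    """A positive series drawn near the GM(1,1) data-generating process."""
    from greycast import SyntheticSpec, generate_noisy

    a = rng.uniform(-0.25, 0.25)
    C = rng.uniform(1.0, 100.0)
    b = C * rng.uniform(0.5, 2.0)
    spec = SyntheticSpec(
        a_true=a, b_true=b, C_true=C, n=n,
        noise_sd=rng.uniform(0.0, 0.05), seed=int(rng.integers(2**31)),
    )
    return generate_noisy(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
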