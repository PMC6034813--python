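import numpy as np
import pytest

from migscale import City, CitySystem, PowerLawFit
from migscale.beta_curve import BetaCurve


def make_planar_system(populations, coords, countryside=0):
    """Planar (Euclidean) toy system; coords are (x, y) pairs in km-like units."""
    cities = [
        City(id=f"c{k}", population=int(p), lon=float(x), lat=float(y))
        for k, (p, (x, y)) in enumerate(zip(populations, coords))
    ]
    return CitySystem(cities, countryside_population=countryside, metric="euclidean")


def make_fit(beta, log_alpha, se_beta=0.01, se_log_alpha=0.1, n_obs=10):
    return PowerLawFit(
        beta_hat=beta,
        se_beta=se_beta,
        log_alpha_hat=log_alpha,
        se_log_alpha=se_log_alpha,
        adj_r2=0.9,
        n_obs=n_obs,
    )


@pytest.fixture
def toy_system():
    """Three cities on a line, planar distances."""
    return make_planar_system([1000, 3000, 5000], [(0, 0), (10, 0), (20, 0)])


@pytest.fixture
def flat_curve():
    return BetaCurve.constant(1.0, (1.0, 1e9))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
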