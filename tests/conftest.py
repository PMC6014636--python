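import numpy as np
import pytest

from antestia.risk_indices import DAYS_PER_YEAR, DailyTemperatureSeries
from antestia.species_models import StageModelSet, TemperatureResponse
from antestia.synthetic_data import (
    default_species_params,
    gen_station_temperatures,
    gen_transect_dem,
)


@pytest.fixture(scope="session")
def models():
    """The calibrated default species set."""
    return default_species_params()


@pytest.fixture(scope="session")
def dem():
    return gen_transect_dem(seed=0)


@pytest.fixture(scope="session")
def stations(dem):
    return gen_station_temperatures(dem, seed=0)


def constant_series(temp, elevation=1200.0, station_id="C", spread=0.0):
    t = np.full(DAYS_PER_YEAR, float(temp))
    return DailyTemperatureSeries(
        station_id=station_id, lon=37.45, lat=-3.3, elevation=elevation,
        tmin=t - spread, tmax=t + spread,
    )


def simple_model_set(
    n_stages=2,
    rate_max=0.2,
    mortality=0.1,
    f_max=30.0,
    sigma=4.0,
    t_opt=25.0,
    sen_a=0.01,
    sen_b=0.0,
    sex_ratio=0.5,
):
    """A small fully-synthetic stage set with wide, well-behaved responses."""
    stages = tuple(f"st{i}" for i in range(n_stages))
    dev = {
        st: TemperatureResponse(
            "development_rate", "beta",
            {"r_max": rate_max * (1 + 0.2 * i), "t_min": 0.0, "t_opt": 30.0,
             "t_max": 45.0}, st)
        for i, st in enumerate(stages)
    }
    mort = {
        st: TemperatureResponse("immature_mortality", "constant", {"m": mortality}, st)
        for st in stages
    }
    return StageModelSet(
        stages=stages,
        development=dev,
        mortality=mort,
        fecundity=TemperatureResponse(
            "fecundity", "gaussian", {"f_max": f_max, "t_opt": t_opt, "sigma": sigma}),
        senescence=TemperatureResponse(
            "senescence_rate", "exponential", {"a": sen_a, "b": sen_b}),
        sex_ratio=sex_ratio,
    )


def random_model_set(rng: np.random.Generator) -> StageModelSet:
    """A random valid stage set for property tests."""
    n_stages = int(rng.integers(1, 7))
    return simple_model_set(
        n_stages=n_stages,
        rate_max=float(rng.uniform(0.02, 0.5)),
        mortality=float(rng.uniform(0.0, 0.6)),
        f_max=float(rng.uniform(2.0, 200.0)),
        sigma=float(rng.uniform(1.0, 8.0)),
        t_opt=float(rng.uniform(15.0, 30.0)),
        sen_a=float(rng.uniform(0.005, 0.05)),
        sen_b=float(rng.uniform(0.0, 0.05)),
        sex_ratio=float(rng.uniform(0.3, 0.7)),
    )
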