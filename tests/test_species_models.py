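"""Thermal-response families and life-table demography."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antestia.families import ConfigurationError
from antestia.params_io import read_species_file, write_species_file
from antestia.species_models import (
    TemperatureResponse,
    compare_constant_vs_fluctuating,
    eval_response,
    immature_survival,
    life_table_at,
)
from antestia.synthetic_data import default_species_params

from conftest import random_model_set, simple_model_set


class TestEvalResponse:
    def test_development_rate_zero_at_and_beyond_limits(self, models):
        rate = models.development["egg"]
        for t in (14.6, 10.0, -5.0, 32.9, 35.0):
            assert eval_response(rate, t) == 0.0
        assert eval_response(rate, 25.0) > 0.0

    def test_development_rate_nonnegative_and_continuous_at_limits(self, models):
        grid = np.arange(-5.0, 45.0, 0.01)
        rate = models.development["N3"]
        assert np.all(rate.evaluate(grid) >= 0.0)
        # the rate vanishes continuously as the thermal limits are approached
        assert rate.evaluate(14.6 + 1e-9) < 1e-6
        assert rate.evaluate(32.9 - 1e-9) < 1e-3

    def test_development_argmax_matches_stored_optimum(self, models):
        rate = models.development["egg"]
        grid = np.arange(14.6, 32.9, 0.01)
        argmax = grid[np.argmax(rate.evaluate(grid))]
        assert abs(argmax - rate.params["t_opt"]) <= 0.01

    def test_mortality_bounded_to_unit_interval(self, models):
        grid = np.linspace(-10.0, 50.0, 500)
        m = models.mortality["N1"].evaluate(grid)
        assert np.all((m >= 0.0) & (m <= 1.0))

    def test_fecundity_nonnegative(self, models):
        grid = np.linspace(-10.0, 50.0, 200)
        assert np.all(models.fecundity.evaluate(grid) >= 0.0)

    def test_unknown_family_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            TemperatureResponse("development_rate", "no-such-family", {"a": 1.0})

    def test_wrong_arity_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            TemperatureResponse("development_rate", "briere1", {"a": 1.0})
        with pytest.raises(ConfigurationError):
            TemperatureResponse(
                "development_rate", "briere1",
                {"a": 1.0, "t_min": 10.0, "t_max": 35.0, "bogus": 1.0})

    def test_family_kind_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            TemperatureResponse("fecundity", "briere1",
                                {"a": 1.0, "t_min": 10.0, "t_max": 35.0})


class TestImmatureSurvival:
    def test_calibrated_mortality_at_30C_is_89_percent(self, models):
        _, total = immature_survival(models, 30.0)
        assert total == pytest.approx(0.11, abs=0.005)

    def test_product_of_stagewise_survivals(self, models):
        per_stage, total = immature_survival(models, 24.0)
        assert total == pytest.approx(np.prod(list(per_stage.values())), abs=1e-12)
        assert all(0.0 <= s <= 1.0 for s in per_stage.values())

    def test_zero_mortality_gives_unit_survival(self):
        ms = simple_model_set(mortality=0.0)
        _, total = immature_survival(ms, 20.0)
        assert total == 1.0

    def test_survival_optimum_in_22_24_band(self, models):
        grid = np.arange(10.0, 35.01, 0.5)
        surv = np.array([immature_survival(models, t)[1] for t in grid])
        assert 22.0 <= grid[np.argmax(surv)] <= 24.0


class TestLifeTableAt:
    def test_positive_growth_exactly_on_19_25_window(self, models):
        grid = np.round(np.arange(10.0, 35.01, 0.5), 6)
        positive = grid[[life_table_at(models, t).rm > 0 for t in grid]]
        assert positive.min() == 19.0
        assert positive.max() == 25.0

    def test_generations_per_year_within_published_range(self, models):
        for t in np.arange(19.0, 25.01, 0.5):
            gens = 365.0 / life_table_at(models, t).t
            assert 2.6 <= gens <= 4.4

    def test_identities_lambda_dt_r0(self, models):
        for t in (17.0, 20.0, 23.0, 26.0):
            lt = life_table_at(models, t)
            assert abs(lt.lambda_ - math.exp(lt.rm)) < 1e-9
            assert abs(lt.rm * lt.t - math.log(lt.r0)) < 1e-9
            if lt.rm > 0:
                assert abs(lt.dt * lt.rm - math.log(2.0)) < 1e-9
            assert lt.r0 <= lt.grr + 1e-12

    def test_lethal_temperature_reports_rm_floor(self):
        ms = simple_model_set(mortality=1.0)
        lt = life_table_at(ms, 20.0)
        assert lt.r0 == 0.0
        assert lt.rm == ms.rm_floor
        assert lt.lambda_ == pytest.approx(math.exp(ms.rm_floor))
        assert math.isinf(lt.dt)

    def test_development_time_decreases_while_rates_increase(self, models):
        # Brière rates increase up to ~28 °C; development time must fall
        temps = np.arange(16.0, 27.01, 0.5)
        dev_time = [life_table_at(models, t).t - 0.5 / models.senescence.evaluate(t)
                    for t in temps]
        assert np.all(np.diff(dev_time) < 0)

    def test_identity_suite_on_random_parameter_sets(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            ms = random_model_set(rng)
            t = float(rng.uniform(5.0, 40.0))
            lt = life_table_at(ms, t)
            assert abs(lt.lambda_ - math.exp(lt.rm)) < 1e-9
            if lt.r0 > 0 and not math.isinf(lt.t):
                assert abs(lt.rm * lt.t - math.log(lt.r0)) < 1e-9
            if lt.rm > 0:
                assert abs(lt.dt * lt.rm - math.log(2.0)) < 1e-9
            assert lt.r0 <= lt.grr + 1e-12


def cohort_life_table(ms, temp):
    """Independent day-stepping cohort oracle at constant temperature.

    Advances a cohort day by day: development accumulates per stage until
    it reaches 1 (fractional final day), stage mortality applies on stage
    completion, adults age until the senescence accumulation reaches 1,
    laying eggs at a constant daily rate while alive.
    """
    age = 0.0
    survival = 1.0
    for stage in ms.stages:
        rate = float(ms.development[stage].evaluate(temp))
        if rate <= 0:
            return None
        acc = 0.0
        while acc + rate < 1.0 - 1e-12:
            acc += rate
            age += 1.0
        age += (1.0 - acc) / rate
        survival *= 1.0 - float(ms.mortality[stage].evaluate(temp))

    sen = float(ms.senescence.evaluate(temp))
    lifespan_acc, adult_days = 0.0, 0.0
    while lifespan_acc + sen < 1.0 - 1e-12:
        lifespan_acc += sen
        adult_days += 1.0
    adult_days += (1.0 - lifespan_acc) / sen

    fec = float(ms.fecundity.evaluate(temp))
    daily_eggs = ms.sex_ratio * fec / adult_days
    # day-partitioned l_x m_x sums over the adult window [age, age+adult_days]
    r0 = 0.0
    weighted_age = 0.0
    x = age
    remaining = adult_days
    while remaining > 1e-12:
        step = min(1.0, remaining)
        m_x = daily_eggs * step * survival
        r0 += m_x
        weighted_age += m_x * (x + step / 2.0)
        x += step
        remaining -= step
    t_gen = weighted_age / r0
    rm = math.log(r0) / t_gen
    return {"GRR": ms.sex_ratio * fec, "R0": r0, "T": t_gen, "rm": rm}


class TestCohortOracle:
    def test_closed_form_matches_cohort_simulation(self):
        rng = np.random.default_rng(777)
        checked = 0
        while checked < 20:
            ms = random_model_set(rng)
            t = float(rng.uniform(10.0, 32.0))
            oracle = cohort_life_table(ms, t)
            if oracle is None or oracle["R0"] <= 0:
                continue
            lt = life_table_at(ms, t)
            for key, value in (("GRR", lt.grr), ("R0", lt.r0),
                               ("T", lt.t), ("rm", lt.rm)):
                assert value == pytest.approx(oracle[key], rel=1e-6), key
            checked += 1


class TestFluctuatingComparison:
    def test_constant_series_has_zero_relative_differences(self, models):
        comp = compare_constant_vs_fluctuating(
            models, np.full(30, 22.0), np.full(30, 22.0))
        assert all(abs(v) < 1e-12 for v in comp.relative_difference.values())

    def test_zero_amplitude_equals_constant(self, models):
        comp = compare_constant_vs_fluctuating(
            models, np.full(10, 22.0), np.full(10, 22.0))
        for key, flu in comp.fluctuating.as_dict().items():
            assert flu == pytest.approx(comp.constant.as_dict()[key], rel=1e-12)

    def test_fluctuation_reduces_net_reproduction(self, models):
        # ±5 °C swings around 22 °C: hazard averaging (Jensen) cuts R0
        comp = compare_constant_vs_fluctuating(
            models, np.full(60, 17.0), np.full(60, 27.0))
        assert comp.mean_temperature == pytest.approx(22.0, abs=1e-9)
        assert comp.fluctuating.r0 <= comp.constant.r0

    def test_empty_series_rejected(self, models):
        with pytest.raises(ValueError):
            compare_constant_vs_fluctuating(models, [], [])


class TestSpeciesFile:
    def test_round_trip_is_lossless(self, models, tmp_path):
        path = tmp_path / "species.ini"
        write_species_file(models, path)
        loaded = read_species_file(path)
        assert loaded.stages == models.stages
        assert loaded.sex_ratio == models.sex_ratio
        assert loaded.rm_floor == models.rm_floor
        for st in models.stages:
            assert loaded.development[st].params == models.development[st].params
            assert loaded.mortality[st].params == models.mortality[st].params
        assert loaded.fecundity.params == models.fecundity.params
        assert loaded.senescence.params == models.senescence.params

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_species_file(tmp_path / "nope.ini")


@settings(derandomize=True, max_examples=60)
@given(
    mortality=st.floats(0.0, 0.99),
    temp=st.floats(5.0, 40.0),
    sex_ratio=st.floats(0.2, 1.0),
)
def test_life_table_invariants_hold_generally(mortality, temp, sex_ratio):
    ms = simple_model_set(mortality=mortality, sex_ratio=sex_ratio)
    lt = life_table_at(ms, temp)
    assert abs(lt.lambda_ - math.exp(lt.rm)) < 1e-9
    assert lt.r0 <= lt.grr + 1e-12
    assert lt.t > 0


def test_default_set_loaded_from_file_reproduces_life_table(tmp_path):
    models = default_species_params()
    path = tmp_path / "sp.ini"
    write_species_file(models, path)
    loaded = read_species_file(path)
    for t in (19.0, 23.0, 30.0):
        assert life_table_at(loaded, t) == life_table_at(models, t)
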