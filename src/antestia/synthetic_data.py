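"""Synthetic study-system generators.

Everything the pipeline consumes can be generated here with the
statistical structure of the Kilimanjaro coffee transect study system:
a ~11 × 2 km elevation ramp (1000–1700 m asl), nine temperature loggers
whose annual means fall from ~23 °C at the bottom to ~20 °C at the top,
a moderate-warming 2055 scenario expressed as additive daily deltas, and
24 coffee farms surveyed over four seasons with counts that increase
with elevation and are overdispersed.

The default species parameter set is synthetic but calibrated: its
responses are constrained to reproduce the published thermal biology of
the antestia bug (development limits 14.6–32.9 °C, positive intrinsic
growth only on 19–25 °C, 2.6–4.4 potential generations per year in that
range, 89 % total immature mortality at 30 °C, and a survival optimum at
22–24 °C).  :func:`thermal_constraint_report` re-checks all five
constraints at any time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .risk_indices import DAYS_PER_YEAR, DailyTemperatureSeries
from .spatial_mapping import DEMGrid, GridSpec
from .species_models import StageModelSet, TemperatureResponse, immature_survival, life_table_at

__all__ = [
    "TABLE_DELTAS",
    "ScenarioSpec",
    "default_species_params",
    "thermal_constraint_report",
    "gen_transect_dem",
    "gen_station_temperatures",
    "default_scenario",
    "gen_future_scenario",
    "gen_farm_counts",
    "make_fixtures",
]

METRES_PER_DEGREE = 111_320.0

# --- calibrated default species constants ---------------------------------

_T_MIN, _T_MAX = 14.6, 32.9
_T_OPT_DEV = 28.287818385368126          # Brière-1 argmax for these limits
_B25 = 730.7804047728702                 # Brière shape factor at 25 °C
_STAGE_DURATIONS_25C = {                 # days per stage at 25 °C
    "egg": 4.0, "N1": 3.5, "N2": 4.0, "N3": 5.0, "N4": 6.0, "N5": 7.5,
}
_MORTALITY_PARAMS = {
    "t_ref": 23.0, "c0": 0.015, "c_cold": 0.024, "c_hot": 0.0005,
    "t_hot": 26.0, "w_hot": 4.074932304760336, "p_hot": 60.0,
    "t_cold": 8.0, "w_cold": 2.0, "p_cold": 30.0,
}
_FECUNDITY_PARAMS = {"f_max": 45.0, "f_floor": 2.2, "t_opt": 24.4,
                     "sigma_left": 6.614970236626375,
                     "sigma_right": 0.21922964806336528}
_SENESCENCE_PARAMS = {"a": 1.0 / (110.0 * math.exp(0.5)), "b": 0.02}


def default_species_params() -> StageModelSet:
    """The calibrated default antestia-bug stage model set."""
    dev = {
        st: TemperatureResponse(
            "development_rate", "briere1",
            {"a": 1.0 / (dur * _B25), "t_min": _T_MIN, "t_max": _T_MAX,
             "t_opt": _T_OPT_DEV},
            stage=st,
        )
        for st, dur in _STAGE_DURATIONS_25C.items()
    }
    mort = {
        st: TemperatureResponse("immature_mortality", "stress_hazard",
                                dict(_MORTALITY_PARAMS), stage=st)
        for st in _STAGE_DURATIONS_25C
    }
    return StageModelSet(
        stages=tuple(_STAGE_DURATIONS_25C),
        development=dev,
        mortality=mort,
        fecundity=TemperatureResponse("fecundity", "skew_gaussian", dict(_FECUNDITY_PARAMS)),
        senescence=TemperatureResponse("senescence_rate", "exponential",
                                       dict(_SENESCENCE_PARAMS)),
        sex_ratio=0.5,
        name="Antestiopsis thunbergii (synthetic calibrated default)",
    )


def thermal_constraint_report(models: StageModelSet | None = None,
                              grid_step: float = 0.5) -> Dict[str, dict]:
    """Re-run the five thermal-biology calibration checks.

    Returns a dict keyed by constraint name with ``value`` and ``ok``.
    """
    models = models or default_species_params()
    grid = np.round(np.arange(10.0, 35.0 + grid_step / 2, grid_step), 6)

    rate = models.development[models.stages[0]]
    limits_ok = all(
        rate.evaluate(t) == 0.0 for t in (_T_MIN, _T_MIN - 1.0, _T_MAX, _T_MAX + 1.0)
    ) and rate.evaluate(22.0) > 0.0

    rm = np.array([life_table_at(models, t).rm for t in grid])
    window = grid[rm > 0]
    window_ok = window.size > 0 and window.min() == 19.0 and window.max() == 25.0

    in_range = grid[(grid >= 19.0) & (grid <= 25.0)]
    gens = np.array([365.0 / life_table_at(models, t).t for t in in_range])
    gens_ok = bool(gens.min() >= 2.6 and gens.max() <= 4.4)

    _, s30 = immature_survival(models, 30.0)
    mort30_ok = abs((1.0 - s30) - 0.89) < 0.01

    surv = np.array([immature_survival(models, t)[1] for t in grid])
    t_best = float(grid[np.argmax(surv)])
    optimum_ok = 22.0 <= t_best <= 24.0

    return {
        "development_limits": {"value": (_T_MIN, _T_MAX), "ok": bool(limits_ok)},
        "positive_growth_window": {
            "value": (float(window.min()), float(window.max())) if window.size else None,
            "ok": bool(window_ok)},
        "generations_per_year": {"value": (float(gens.min()), float(gens.max())),
                                 "ok": bool(gens_ok)},
        "immature_mortality_30C": {"value": float(1.0 - s30), "ok": bool(mort30_ok)},
        "survival_optimum": {"value": t_best, "ok": bool(optimum_ok)},
    }


# --- transect DEM ----------------------------------------------------------


def gen_transect_dem(
    length_km: float = 11.0,
    width_km: float = 2.0,
    elev_range: Tuple[float, float] = (1000.0, 1700.0),
    cell_m: float = 100.0,
    roughness_m: float = 5.0,
    seed: int = 0,
    origin: Tuple[float, float] = (37.44, -3.27),
) -> DEMGrid:
    """A north-up transect DEM: monotone south→north elevation ramp plus
    seeded low-amplitude roughness, rescaled so min/max hit ``elev_range``
    exactly.  ``origin`` is the NW corner (lon, lat)."""
    if length_km <= 0 or width_km <= 0:
        raise ValueError("transect dimensions must be positive")
    if cell_m > width_km * 1000.0:
        raise ValueError("cell size exceeds the transect width")
    nrows = int(round(length_km * 1000.0 / cell_m))
    ncols = int(round(width_km * 1000.0 / cell_m))
    rng = np.random.default_rng(seed)

    ramp = np.linspace(1.0, 0.0, nrows)[:, None] * np.ones((1, ncols))  # row 0 = north = high
    lo, hi = elev_range
    elev = lo + ramp * (hi - lo)

    # smooth seeded roughness: filtered white noise, zero-mean
    noise = rng.normal(0.0, 1.0, size=(nrows, ncols))
    kernel = np.ones(5) / 5.0
    for axis in (0, 1):
        noise = np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same"), axis, noise)
    noise -= noise.mean()
    elev = elev + roughness_m * noise / max(noise.std(), 1e-12)
    # exact range
    elev = lo + (elev - elev.min()) * (hi - lo) / (elev.max() - elev.min())

    cell_deg = cell_m / METRES_PER_DEGREE
    grid = GridSpec(nrows=nrows, ncols=ncols, x_origin=origin[0],
                    y_origin=origin[1], cell=cell_deg)
    return DEMGrid(grid=grid, elevation=elev)


# --- station temperatures --------------------------------------------------

#: Transect temperature-change rows (elevation m, Δt_min °C, Δt_max °C)
#: from the RCP4.5 2055 projection contrast against the 2013 loggers.
TABLE_DELTAS = np.array([
    [1081.0, 0.10, 1.83],
    [1249.0, 0.11, 0.10],
    [1419.0, 0.27, 0.57],
    [1533.0, 0.34, 0.76],
    [1705.0, 0.17, 0.76],
])

#: Lapse rate regressed from the five logger rows above (°C per km) and the
#: standard-atmosphere alternative.
LAPSE_TRANSECT = 5.73
LAPSE_STANDARD = 6.5

COOLEST_DOY = 196  # mid-July: centre of the June–August cool season


def gen_station_temperatures(
    dem: DEMGrid,
    n_stations: int = 9,
    sea_level_mean: float = 28.9,
    lapse_rate: float = LAPSE_TRANSECT,
    seasonal_amplitude: float = 1.8,
    diurnal_range: float = 12.0,
    noise_sd: Tuple[float, float] = (0.8, 3.0),
    local_noise_sd: float = 0.2,
    lower_margin: float = 0.15,
    seed: int = 0,
) -> List[DailyTemperatureSeries]:
    """Daily min/max series for loggers spread along the transect.

    The daily midpoint is ``sea_level_mean − lapse_rate·elev_km`` plus a
    single-harmonic seasonal cycle (coolest in mid-July).  Minima and
    maxima sit half the diurnal range below/above it; day-to-day weather
    anomalies (``noise_sd`` = (SD of t_min, SD of t_max), the maxima
    being much noisier in the field record) are regional — shared by all
    loggers, as cloud cover is on a 11 × 2 km transect — with a small
    independent per-logger component (``local_noise_sd``).  Loggers span
    the upper 90 % of the elevation range (the field deployment started
    ~80 m above the transect floor).
    """
    rng = np.random.default_rng(seed)
    nrows, ncols = dem.elevation.shape
    # loggers zig-zag across the transect width, as deployed in farms on
    # both sides of the ridge line
    cols = [ncols // 4, ncols // 2, (3 * ncols) // 4]
    col = ncols // 2
    profile = dem.elevation[:, col]
    lo = profile.min() + lower_margin * np.ptp(profile)
    targets = np.linspace(lo, profile.max(), n_stations)
    rows = [int(np.argmin(np.abs(profile - t))) for t in targets]
    lon, lat = dem.grid.cell_centers()
    days = np.arange(1, DAYS_PER_YEAR + 1)
    seasonal = -seasonal_amplitude * np.cos(2.0 * np.pi * (days - COOLEST_DOY) / DAYS_PER_YEAR)
    # anomalies are centred so the configured annual mean is exact
    regional_min = rng.normal(0.0, noise_sd[0], DAYS_PER_YEAR)
    regional_max = rng.normal(0.0, noise_sd[1], DAYS_PER_YEAR)
    regional_min -= regional_min.mean()
    regional_max -= regional_max.mean()

    out = []
    for i, r in enumerate(rows):
        c = cols[i % len(cols)]
        elev = float(dem.elevation[r, c])
        mean = sea_level_mean - lapse_rate * elev / 1000.0 + seasonal
        local_min = rng.normal(0.0, local_noise_sd, DAYS_PER_YEAR)
        local_max = rng.normal(0.0, local_noise_sd, DAYS_PER_YEAR)
        tmin = mean - diurnal_range / 2.0 + regional_min + local_min - local_min.mean()
        tmax = mean + diurnal_range / 2.0 + regional_max + local_max - local_max.mean()
        tmax = np.maximum(tmax, tmin + 0.1)
        out.append(DailyTemperatureSeries(
            station_id=f"S{i + 1}",
            lon=float(lon[r, c]), lat=float(lat[r, c]), elevation=elev,
            tmin=tmin, tmax=tmax,
        ))
    return out


# --- future scenario -------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """Additive per-station daily temperature deltas for a future scenario."""

    label: str
    deltas: Dict[str, Tuple[float, float]]  # station id -> (Δt_min, Δt_max)

    def __post_init__(self):
        if not self.label:
            raise ValueError("scenario label must be non-empty")
        for sid, (dmin, dmax) in self.deltas.items():
            if not (math.isfinite(dmin) and math.isfinite(dmax)):
                raise ValueError(f"non-finite delta for station {sid}")


def default_scenario(stations: Sequence[DailyTemperatureSeries],
                     label: str = "RCP4.5-2055") -> ScenarioSpec:
    """Moderate-warming deltas interpolated from the five transect rows
    of :data:`TABLE_DELTAS` by station elevation."""
    elev = TABLE_DELTAS[:, 0]
    deltas = {
        s.station_id: (
            float(np.interp(s.elevation, elev, TABLE_DELTAS[:, 1])),
            float(np.interp(s.elevation, elev, TABLE_DELTAS[:, 2])),
        )
        for s in stations
    }
    return ScenarioSpec(label=label, deltas=deltas)


def gen_future_scenario(
    current: Sequence[DailyTemperatureSeries],
    spec: ScenarioSpec,
) -> List[DailyTemperatureSeries]:
    """Apply a scenario's additive deltas to every station, exactly."""
    out = []
    for s in current:
        if s.station_id not in spec.deltas:
            raise ValueError(f"scenario {spec.label!r} lacks station {s.station_id}")
        dmin, dmax = spec.deltas[s.station_id]
        out.append(DailyTemperatureSeries(
            station_id=s.station_id, lon=s.lon, lat=s.lat, elevation=s.elevation,
            tmin=s.tmin + dmin, tmax=s.tmax + dmax,
        ))
    return out


# --- farm survey counts ----------------------------------------------------

DEFAULT_SEASON_EFFECTS = {
    "cool-dry-2014": 0.35,
    "short-rainy-2014": 0.0,
    "warm-dry-2015": -0.35,
    "cool-dry-2015": 0.35,
}


def gen_farm_counts(
    dem: DEMGrid,
    n_farms: int = 24,
    farms_per_band: int = 4,
    band_centres: Sequence[float] = (1100, 1200, 1300, 1400, 1500, 1600),
    glm_truth: Tuple[float, float] = (-3.43, 0.0038),
    dispersion: float = 2.0,
    seasonal_effects: Dict[str, float] | None = None,
    trees_per_farm: int = 15,
    seed: int = 0,
    per_tree: bool = False,
) -> pd.DataFrame:
    """Overdispersed farm-level bug counts along the elevation gradient.

    Farm totals (over ``trees_per_farm`` trees) are negative-binomial with
    log-link mean ``exp(b0 + b1·elev + season_effect)`` and variance
    ``dispersion × mean``; ``dispersion=1`` degenerates to Poisson.  With
    the default truth, densities run from ~0.1 bugs·tree⁻¹ at 1000 m to
    above 1 bugs·tree⁻¹ at the top and cool-season means are about twice
    the warm-season means.
    """
    if len(band_centres) * farms_per_band != n_farms:
        raise ValueError("n_farms must equal bands × farms_per_band")
    if dispersion < 1.0:
        raise ValueError("dispersion must be >= 1")
    seasonal_effects = DEFAULT_SEASON_EFFECTS if seasonal_effects is None else seasonal_effects
    rng = np.random.default_rng(seed)
    b0, b1 = glm_truth

    lon, lat = dem.grid.cell_centers()
    farms = []
    fid = 0
    for centre in band_centres:
        in_band = dem.mask & (np.abs(dem.elevation - centre) <= 50.0)
        idx = np.flatnonzero(in_band.ravel())
        if idx.size < farms_per_band:
            raise ValueError(f"no room for {farms_per_band} farms near {centre} m")
        for cell in rng.choice(idx, size=farms_per_band, replace=False):
            r, c = np.unravel_index(cell, dem.elevation.shape)
            fid += 1
            farms.append((f"F{fid:02d}", float(lon[r, c]), float(lat[r, c]),
                          float(dem.elevation[r, c])))

    # farm totals are drawn first so per-tree decomposition never shifts
    # the random stream: per_tree=True reproduces the same totals
    totals = []
    for season, eff in seasonal_effects.items():
        for farm_id, flon, flat, elev in farms:
            mu = math.exp(b0 + b1 * elev + eff)
            if dispersion == 1.0:
                total = int(rng.poisson(mu))
            else:
                # gamma-Poisson mixture with var = dispersion * mean
                shape = mu / (dispersion - 1.0)
                total = int(rng.poisson(rng.gamma(shape, dispersion - 1.0)))
            totals.append((season, farm_id, flon, flat, elev, total))

    rows = []
    for season, farm_id, flon, flat, elev, total in totals:
        if per_tree:
            tree_counts = rng.multinomial(
                total, np.full(trees_per_farm, 1.0 / trees_per_farm))
            for ti, cnt in enumerate(tree_counts, start=1):
                rows.append({"farm_id": farm_id, "lon": flon, "lat": flat,
                             "elevation_m": elev, "season": season,
                             "tree_index": ti, "count": int(cnt)})
        else:
            rows.append({"farm_id": farm_id, "lon": flon, "lat": flat,
                         "elevation_m": elev, "season": season, "count": total})
    return pd.DataFrame(rows)


# --- one-stop fixtures -----------------------------------------------------


def make_fixtures(outdir, seed: int = 0, cell_m: float = 100.0) -> Dict[str, Path]:
    """Materialise a complete synthetic study directory.

    Writes the DEM (ASCII grid), current and future station series,
    survey counts, the species parameter file, and the scenario deltas;
    returns the path of every artefact.
    """
    from .params_io import write_species_file
    from .risk_indices import write_station_csv
    from .spatial_mapping import write_ascii_grid

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)

    dem = gen_transect_dem(cell_m=cell_m, seed=int(seeds[0]))
    stations = gen_station_temperatures(dem, seed=int(seeds[1]))
    scenario = default_scenario(stations)
    future = gen_future_scenario(stations, scenario)
    survey = gen_farm_counts(dem, seed=int(seeds[2]), per_tree=True)
    species = default_species_params()

    paths = {
        "dem": outdir / "dem.asc",
        "stations_current": outdir / "stations_current.csv",
        "stations_future": outdir / "stations_future.csv",
        "survey": outdir / "survey.csv",
        "species": outdir / "species.ini",
        "scenario": outdir / "scenario.csv",
    }
    write_ascii_grid(dem, paths["dem"])
    write_station_csv(stations, paths["stations_current"])
    write_station_csv(future, paths["stations_future"])
    survey.to_csv(paths["survey"], index=False)
    write_species_file(species, paths["species"])
    pd.DataFrame(
        [{"station_id": sid, "delta_tmin_c": d[0], "delta_tmax_c": d[1],
          "label": scenario.label}
         for sid, d in scenario.deltas.items()]
    ).to_csv(paths["scenario"], index=False)
    return paths
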