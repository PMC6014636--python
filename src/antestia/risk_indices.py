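"""Annual infestation risk indices from daily min/max temperatures.

Three indices summarise a 365-day series of daily temperature extremes:

* **ERI** (establishment risk index): 1 minus the fraction of days on
  which at least one immature stage suffers total mortality; in [0, 1].
* **GI** (generation index): potential generations per year, accumulated
  as Σ_d 1/T_d where T_d is the generation time implied by day *d*'s
  temperature cycle.  At constant temperature this equals 365/T.
* **AI** (activity index): log₁₀ of the product of daily finite rates of
  increase; 10^AI is the potential annual multiplication factor.

Each day's demography is obtained by rate summation over a reconstructed
24-point cosine cycle between the day's minimum and maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .species_models import StageModelSet, demography_from_samples

__all__ = [
    "DAYS_PER_YEAR",
    "DEFAULT_LETHAL_SURVIVAL",
    "DailyTemperatureSeries",
    "RiskIndices",
    "hourly_profile",
    "daily_demography",
    "eri",
    "gi",
    "ai",
    "growth_factor",
    "annual_indices",
    "indices_at_stations",
    "read_station_csv",
    "write_station_csv",
    "write_indices_csv",
]

DAYS_PER_YEAR = 365

#: A stage counts as suffering total mortality on a day when its
#: rate-summed daily survival falls at or below this threshold.
DEFAULT_LETHAL_SURVIVAL = 0.005


@dataclass(frozen=True)
class DailyTemperatureSeries:
    """One georeferenced station year of daily extremes (°C)."""

    station_id: str
    lon: float
    lat: float
    elevation: float
    tmin: np.ndarray
    tmax: np.ndarray

    def __post_init__(self):
        tmin = np.asarray(self.tmin, dtype=float)
        tmax = np.asarray(self.tmax, dtype=float)
        object.__setattr__(self, "tmin", tmin)
        object.__setattr__(self, "tmax", tmax)
        if tmin.shape != (DAYS_PER_YEAR,) or tmax.shape != (DAYS_PER_YEAR,):
            raise ValueError(
                f"{self.station_id}: need exactly {DAYS_PER_YEAR} daily records"
            )
        if np.any(tmin > tmax):
            bad = int(np.argmax(tmin > tmax)) + 1
            raise ValueError(f"{self.station_id}: t_min > t_max on Julian day {bad}")

    @property
    def mean(self) -> float:
        """Annual mean of the daily midpoints (t_min + t_max)/2."""
        return float((self.tmin + self.tmax).mean() / 2.0)


@dataclass(frozen=True)
class RiskIndices:
    """The (ERI, GI, AI) triple for one station or grid cell."""

    eri: float
    gi: float
    ai: float

    def __post_init__(self):
        if not 0.0 <= self.eri <= 1.0:
            raise ValueError(f"ERI out of [0, 1]: {self.eri}")
        if self.gi < 0.0:
            raise ValueError(f"GI negative: {self.gi}")


_HOUR_PHASE = np.cos(2.0 * np.pi * (np.arange(24) - 14) / 24.0)


def hourly_profile(t_min: float, t_max: float, n: int = 24) -> np.ndarray:
    """Cosine within-day temperature cycle.

    ``n`` evenly spaced samples with the minimum at 02:00, the maximum at
    14:00; the sample mean equals (t_min + t_max)/2 exactly.
    """
    if t_min > t_max:
        raise ValueError(f"t_min {t_min} exceeds t_max {t_max}")
    phase = _HOUR_PHASE if n == 24 else np.cos(2.0 * np.pi * (np.arange(n) - 14 * n / 24) / n)
    return (t_min + t_max) / 2.0 + (t_max - t_min) / 2.0 * phase


@dataclass(frozen=True)
class DayDemography:
    """Per-day demographic summary used by the annual indices."""

    lambda_: float
    generation_time: float
    stage_survival: Dict[str, float]
    lethal_stages: Tuple[str, ...]

    @property
    def lethal(self) -> bool:
        return bool(self.lethal_stages)


def _profile_matrix(series: DailyTemperatureSeries) -> np.ndarray:
    half = (series.tmax - series.tmin) / 2.0
    mid = (series.tmax + series.tmin) / 2.0
    return mid[:, None] + half[:, None] * _HOUR_PHASE[None, :]


def daily_demography(
    models: StageModelSet,
    t_min: float,
    t_max: float,
    lethal_survival: float = DEFAULT_LETHAL_SURVIVAL,
) -> DayDemography:
    """Demography of a single day given its temperature extremes."""
    hours = hourly_profile(t_min, t_max)
    params = demography_from_samples(models, hours)
    surv = {
        st: float(np.exp(-models.mortality[st].hazard(hours).mean()))
        for st in models.stages
    }
    lethal = tuple(st for st in models.stages if surv[st] <= lethal_survival)
    return DayDemography(
        lambda_=params.lambda_,
        generation_time=params.t,
        stage_survival=surv,
        lethal_stages=lethal,
    )


def _annual_arrays(
    models: StageModelSet,
    series: DailyTemperatureSeries,
    lethal_survival: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised day loop: (lethal flags, generation times, log10 λ_d)."""
    temps = _profile_matrix(series)  # (365, 24)
    flat = temps.ravel()

    rates_sum_inv = np.zeros(DAYS_PER_YEAR)
    total_hazard = np.zeros(DAYS_PER_YEAR)
    lethal = np.zeros(DAYS_PER_YEAR, dtype=bool)
    for st in models.stages:
        q = models.mortality[st].hazard(flat).reshape(temps.shape).mean(axis=1)
        lethal |= np.exp(-q) <= lethal_survival
        total_hazard += q
        rbar = models.development[st].evaluate(flat).reshape(temps.shape).mean(axis=1)
        with np.errstate(divide="ignore"):
            rates_sum_inv += np.where(rbar > 0.0, 1.0 / np.where(rbar > 0, rbar, 1.0), np.inf)

    fec = models.fecundity.evaluate(flat).reshape(temps.shape).mean(axis=1)
    sen = models.senescence.evaluate(flat).reshape(temps.shape).mean(axis=1)
    lifespan = 1.0 / sen
    t_gen = rates_sum_inv + 0.5 * lifespan
    r0 = np.exp(-total_hazard) * models.sex_ratio * fec

    with np.errstate(divide="ignore", invalid="ignore"):
        rm = np.where(r0 > 0.0, np.log(np.where(r0 > 0, r0, 1.0)) / t_gen, models.rm_floor)
    rm = np.where(np.isinf(t_gen) & (r0 > 0.0), 0.0, rm)
    # the AI accumulates log10 of λ_d floored at exp(rm_floor): a day can
    # never drive the annual product down harder than a fully lethal day
    log10_lambda = np.maximum(rm, models.rm_floor) / np.log(10.0)
    return lethal, t_gen, log10_lambda


def eri(
    series: DailyTemperatureSeries,
    models: StageModelSet,
    lethal_survival: float = DEFAULT_LETHAL_SURVIVAL,
) -> float:
    """Establishment risk index: 1 − (lethal days)/365."""
    lethal, _, _ = _annual_arrays(models, series, lethal_survival)
    return 1.0 - int(lethal.sum()) / DAYS_PER_YEAR


def gi(
    series: DailyTemperatureSeries,
    models: StageModelSet,
    lethal_survival: float = DEFAULT_LETHAL_SURVIVAL,
) -> float:
    """Generation index: Σ_d 1/T_d generations per year."""
    _, t_gen, _ = _annual_arrays(models, series, lethal_survival)
    with np.errstate(divide="ignore"):
        frac = np.where(np.isinf(t_gen), 0.0, 1.0 / t_gen)
    return float(frac.sum())


def ai(
    series: DailyTemperatureSeries,
    models: StageModelSet,
    lethal_survival: float = DEFAULT_LETHAL_SURVIVAL,
) -> float:
    """Activity index: Σ_d log₁₀ λ_d, lethal days at the rm floor."""
    lethal, _, log10_lam = _annual_arrays(models, series, lethal_survival)
    floor = models.rm_floor / np.log(10.0)
    return float(np.where(lethal, floor, log10_lam).sum())


def growth_factor(ai_value: float) -> float:
    """Annual population multiplication factor implied by an AI value."""
    return float(10.0 ** ai_value)


def annual_indices(
    series: DailyTemperatureSeries,
    models: StageModelSet,
    lethal_survival: float = DEFAULT_LETHAL_SURVIVAL,
) -> RiskIndices:
    """All three indices in one pass over the year."""
    lethal, t_gen, log10_lam = _annual_arrays(models, series, lethal_survival)
    with np.errstate(divide="ignore"):
        frac = np.where(np.isinf(t_gen), 0.0, 1.0 / t_gen)
    floor = models.rm_floor / np.log(10.0)
    return RiskIndices(
        eri=1.0 - int(lethal.sum()) / DAYS_PER_YEAR,
        gi=float(frac.sum()),
        ai=float(np.where(lethal, floor, log10_lam).sum()),
    )


def indices_at_stations(
    series_set: Iterable[DailyTemperatureSeries],
    models: StageModelSet,
    lethal_survival: float = DEFAULT_LETHAL_SURVIVAL,
) -> pd.DataFrame:
    """Station-indexed table of risk indices with coordinates and elevation."""
    series_list = list(series_set)
    if not series_list:
        raise ValueError("at least one station series is required")
    ids = [s.station_id for s in series_list]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate station ids: {dupes}")
    rows = []
    for s in series_list:
        idx = annual_indices(s, models, lethal_survival)
        rows.append(
            {"station_id": s.station_id, "lon": s.lon, "lat": s.lat,
             "elevation_m": s.elevation, "eri": idx.eri, "gi": idx.gi, "ai": idx.ai}
        )
    return pd.DataFrame(rows).set_index("station_id")


# ---------------------------------------------------------------------------
# CSV interfaces (long format: one row per station-day)

_STATION_COLUMNS = ["station_id", "lon", "lat", "elevation_m", "julian_day", "tmin_c", "tmax_c"]


def write_station_csv(series_set: Sequence[DailyTemperatureSeries], path) -> None:
    frames = []
    for s in series_set:
        frames.append(pd.DataFrame({
            "station_id": s.station_id, "lon": s.lon, "lat": s.lat,
            "elevation_m": s.elevation,
            "julian_day": np.arange(1, DAYS_PER_YEAR + 1),
            "tmin_c": s.tmin, "tmax_c": s.tmax,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_station_csv(path) -> List[DailyTemperatureSeries]:
    """Load station series; a 366-day (leap) year is reduced by dropping
    day 60 (29 February) and renumbering."""
    df = pd.read_csv(path)
    missing = set(_STATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("station_id", sort=False):
        grp = grp.sort_values("julian_day")
        if len(grp) == DAYS_PER_YEAR + 1:
            grp = grp[grp["julian_day"] != 60]
        if len(grp) != DAYS_PER_YEAR:
            raise ValueError(
                f"{path}: station {sid} has {len(grp)} days, expected {DAYS_PER_YEAR}"
            )
        out.append(DailyTemperatureSeries(
            station_id=str(sid),
            lon=float(grp["lon"].iloc[0]), lat=float(grp["lat"].iloc[0]),
            elevation=float(grp["elevation_m"].iloc[0]),
            tmin=grp["tmin_c"].to_numpy(), tmax=grp["tmax_c"].to_numpy(),
        ))
    return out


def write_indices_csv(table: pd.DataFrame, path) -> None:
    table.reset_index().to_csv(path, index=False)
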