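"""Stage-structured thermal biology and life-table demography.

The life cycle is egg plus five nymphal instars, each with a
temperature-dependent development rate and a cumulative stage mortality,
followed by adults with a temperature-dependent lifetime fecundity and a
senescence (ageing) rate.  At constant temperature the six classical
life-table parameters follow in closed form:

    D(T)    = Σ_i 1 / rate_i(T)          total immature development, days
    s(T)    = Π_i (1 − m_i(T))           total immature survival
    L(T)    = 1 / senescence(T)          adult lifespan, days
    GRR(T)  = sex_ratio · fecundity(T)   daughters per female, gross
    R0(T)   = s(T) · GRR(T)              daughters per female, net
    T_gen   = D(T) + L(T) / 2            mean generation time (egg laying
                                         spread uniformly over adult life)
    r_m     = ln R0 / T_gen              intrinsic rate of increase, day⁻¹
    λ       = exp(r_m)                   finite rate of increase, day⁻¹
    Dt      = ln 2 / r_m                 doubling time (r_m > 0), days

For fluctuating temperatures the same machinery runs on rate summation:
every response is averaged over the supplied temperature samples
(mortalities on the hazard scale) before the life-table identities are
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .families import ConfigurationError, get_family

__all__ = [
    "KINDS",
    "TemperatureResponse",
    "StageModelSet",
    "LifeTableParams",
    "eval_response",
    "immature_survival",
    "life_table_at",
    "compare_constant_vs_fluctuating",
    "demography_from_samples",
]

KINDS = ("development_rate", "immature_mortality", "fecundity", "senescence_rate")

#: r_m assigned when net reproduction is exactly zero (see docs/methods.md).
DEFAULT_RM_FLOOR = -0.02


@dataclass(frozen=True)
class TemperatureResponse:
    """One parameterised thermal response, evaluable at any temperature."""

    kind: str
    family: str
    params: Dict[str, float]
    stage: str | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown response kind {self.kind!r}")
        fam = get_family(self.family)
        if self.kind not in fam.kinds:
            raise ConfigurationError(
                f"family {self.family!r} cannot serve kind {self.kind!r}"
            )
        names = set(self.params)
        if not (fam.required <= names <= fam.required | fam.optional):
            raise ConfigurationError(
                f"family {self.family!r} expects parameters {sorted(fam.required)}"
                f" (optional {sorted(fam.optional)}), got {sorted(names)}"
            )
        for k, v in self.params.items():
            if not math.isfinite(float(v)):
                raise ConfigurationError(f"non-finite parameter {k}={v!r}")

    def evaluate(self, temp):
        """Response value at ``temp`` (°C); scalar in, scalar out."""
        fam = get_family(self.family)
        value = fam.func(self.params, np.asarray(temp, dtype=float))
        if self.kind == "immature_mortality":
            value = np.clip(value, 0.0, 1.0)
        return float(value) if np.isscalar(temp) else value

    def hazard(self, temp):
        """Cumulative mortality hazard −ln(1 − m); mortality kinds only."""
        if self.kind != "immature_mortality":
            raise ConfigurationError("hazard is defined for immature_mortality only")
        fam = get_family(self.family)
        t = np.asarray(temp, dtype=float)
        if fam.hazard is not None:
            q = fam.hazard(self.params, t)
        else:
            m = np.clip(fam.func(self.params, t), 0.0, 1.0)
            with np.errstate(divide="ignore"):
                q = -np.log1p(-m)
        return float(q) if np.isscalar(temp) else q

    def optimum(self) -> float:
        """Temperature (°C) maximising the response.

        Uses a stored ``t_opt`` parameter when the family carries one,
        otherwise a bounded numerical search.
        """
        if "t_opt" in self.params:
            return float(self.params["t_opt"])
        lo = float(self.params.get("t_min", -10.0))
        hi = float(self.params.get("t_max", 45.0))
        res = minimize_scalar(
            lambda t: -float(self.evaluate(t)), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        return float(res.x)


def eval_response(model: TemperatureResponse, temp):
    """Functional alias for :meth:`TemperatureResponse.evaluate`."""
    return model.evaluate(temp)


@dataclass(frozen=True)
class StageModelSet:
    """The full thermal model of a species.

    ``stages`` fixes the immature stage order; every stage carries exactly
    one development-rate and one mortality response.
    """

    stages: Tuple[str, ...]
    development: Dict[str, TemperatureResponse]
    mortality: Dict[str, TemperatureResponse]
    fecundity: TemperatureResponse
    senescence: TemperatureResponse
    sex_ratio: float = 0.5
    rm_floor: float = DEFAULT_RM_FLOOR
    name: str = "unnamed"

    def __post_init__(self):
        if not self.stages:
            raise ConfigurationError("at least one immature stage is required")
        for table, kind in ((self.development, "development_rate"),
                            (self.mortality, "immature_mortality")):
            missing = set(self.stages) - set(table)
            if missing:
                raise ConfigurationError(f"stages missing a {kind}: {sorted(missing)}")
            for st in self.stages:
                if table[st].kind != kind:
                    raise ConfigurationError(f"{st}: expected a {kind} response")
        if self.fecundity.kind != "fecundity":
            raise ConfigurationError("fecundity response has the wrong kind")
        if self.senescence.kind != "senescence_rate":
            raise ConfigurationError("senescence response has the wrong kind")
        if not 0.0 < self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must lie in (0, 1]")

    def with_rm_floor(self, rm_floor: float) -> "StageModelSet":
        return replace(self, rm_floor=float(rm_floor))


@dataclass(frozen=True)
class LifeTableParams:
    """The six simulated demographic parameters at one temperature regime.

    Attributes
    ----------
    grr : float
        Gross reproductive rate, daughters · female⁻¹.
    r0 : float
        Net reproductive rate, daughters · female⁻¹.
    t : float
        Mean generation time, days (``inf`` when development is impossible).
    dt : float
        Population doubling time, days; ``inf`` when ``rm <= 0``.
    rm : float
        Intrinsic rate of increase, day⁻¹.
    lambda_ : float
        Finite rate of increase ``exp(rm)``, day⁻¹.
    """

    grr: float
    r0: float
    t: float
    dt: float
    rm: float
    lambda_: float

    def as_dict(self) -> Dict[str, float]:
        return {"GRR": self.grr, "R0": self.r0, "T": self.t,
                "Dt": self.dt, "rm": self.rm, "lambda": self.lambda_}


def immature_survival(models: StageModelSet, temp) -> Tuple[Dict[str, float], float]:
    """Per-stage survival probabilities and their product at ``temp``."""
    per_stage = {
        st: float(np.clip(1.0 - models.mortality[st].evaluate(temp), 0.0, 1.0))
        for st in models.stages
    }
    total = float(np.prod(list(per_stage.values())))
    return per_stage, total


def demography_from_samples(models: StageModelSet, temps: np.ndarray) -> LifeTableParams:
    """Life-table parameters for a temperature regime given as samples.

    Rate summation: development, fecundity and senescence responses are
    averaged arithmetically over ``temps``; mortality is averaged on the
    hazard scale, so a single sample at a fully lethal temperature is
    enough to extinguish stage survival.
    """
    temps = np.asarray(temps, dtype=float).ravel()
    if temps.size == 0:
        raise ValueError("temperature sample array is empty")
    if not np.all(np.isfinite(temps)):
        raise ValueError("temperature samples must be finite")

    rates = np.array([models.development[st].evaluate(temps).mean() for st in models.stages])
    hazards = np.array([models.mortality[st].hazard(temps).mean() for st in models.stages])
    fec = float(models.fecundity.evaluate(temps).mean())
    sen = float(models.senescence.evaluate(temps).mean())
    if sen <= 0.0:
        raise RuntimeError("senescence rate must be positive (infinite adult lifespan)")

    with np.errstate(divide="ignore"):
        dev_time = float(np.sum(np.where(rates > 0.0, 1.0 / np.where(rates > 0, rates, 1.0), np.inf)))
    survival = float(np.exp(-np.sum(hazards)))
    lifespan = 1.0 / sen
    grr = models.sex_ratio * fec
    r0 = survival * grr
    t_gen = dev_time + 0.5 * lifespan
    if t_gen <= 0.0:
        raise RuntimeError("non-positive generation time: invalid model set")

    if r0 == 0.0:
        rm = models.rm_floor
    elif math.isinf(t_gen):
        rm = 0.0
    else:
        rm = math.log(r0) / t_gen
    lam = math.exp(rm)
    dt = math.log(2.0) / rm if rm > 0.0 else math.inf
    return LifeTableParams(grr=grr, r0=r0, t=t_gen, dt=dt, rm=rm, lambda_=lam)


def life_table_at(models: StageModelSet, temp: float) -> LifeTableParams:
    """Life-table parameters at a constant temperature (°C)."""
    return demography_from_samples(models, np.array([float(temp)]))


@dataclass(frozen=True)
class FluctuationComparison:
    """Constant-vs-fluctuating validation report (no pass/fail judgement)."""

    mean_temperature: float
    fluctuating: LifeTableParams
    constant: LifeTableParams
    relative_difference: Dict[str, float]

    def to_rows(self) -> List[Dict[str, float]]:
        rows = []
        flu, con = self.fluctuating.as_dict(), self.constant.as_dict()
        for key in flu:
            rows.append({"parameter": key, "fluctuating": flu[key],
                         "constant": con[key],
                         "relative_difference": self.relative_difference[key]})
        return rows


def compare_constant_vs_fluctuating(
    models: StageModelSet,
    tmin: Sequence[float],
    tmax: Sequence[float],
    samples_per_day: int = 24,
) -> FluctuationComparison:
    """Compare demography under a fluctuating series against constant-T.

    ``tmin``/``tmax`` are paired daily extremes (any length ≥ 1); the
    within-day cycle is reconstructed with the same cosine profile used by
    the risk indices, the pooled hourly samples drive a rate-summation
    life table, and the result is set against the life table at the pooled
    mean temperature.
    """
    from .risk_indices import hourly_profile  # local import avoids a cycle

    tmin = np.asarray(tmin, dtype=float).ravel()
    tmax = np.asarray(tmax, dtype=float).ravel()
    if tmin.size == 0:
        raise ValueError("empty temperature series")
    if tmin.shape != tmax.shape:
        raise ValueError("tmin and tmax must have the same length")
    hours = np.concatenate(
        [hourly_profile(lo, hi, n=samples_per_day) for lo, hi in zip(tmin, tmax)]
    )
    fluctuating = demography_from_samples(models, hours)
    mean_t = float(hours.mean())
    constant = life_table_at(models, mean_t)

    rel = {}
    for key, f in fluctuating.as_dict().items():
        c = constant.as_dict()[key]
        if f == c:  # covers inf == inf and exact zeros
            rel[key] = 0.0
        else:
            denom = abs(c) if c != 0 else 1.0
            rel[key] = (f - c) / denom
    return FluctuationComparison(mean_t, fluctuating, constant, rel)
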