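"""Named temperature-response function families.

Each family maps a parameter dictionary and a temperature (°C, scalar or
array) to a response value: a development rate (day⁻¹), a cumulative
immature-stage mortality probability, a lifetime fecundity (eggs·female⁻¹)
or a senescence (ageing) rate (day⁻¹).  Families are selected by name in
the species parameter file, so unknown names or wrong parameter sets are
configuration errors, not runtime surprises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet

import numpy as np

__all__ = ["ConfigurationError", "Family", "FAMILIES", "get_family"]


class ConfigurationError(ValueError):
    """Unknown family name or malformed parameter vector."""


@dataclass(frozen=True)
class Family:
    """A named response-function family.

    Parameters
    ----------
    name : str
        Identifier used in species parameter files.
    kinds : frozenset of str
        Response kinds this family may serve.
    required : frozenset of str
        Parameter names that must be present.
    optional : frozenset of str
        Parameter names that may be present (e.g. a stored optimum).
    func : callable
        ``func(params, temp_array) -> value_array``.
    hazard : callable, optional
        For mortality families: the native cumulative hazard
        ``-ln(1 - m)``, numerically safe where ``m -> 1``.
    """

    name: str
    kinds: FrozenSet[str]
    required: FrozenSet[str]
    func: Callable[[Dict[str, float], np.ndarray], np.ndarray]
    optional: FrozenSet[str] = field(default_factory=frozenset)
    hazard: Callable[[Dict[str, float], np.ndarray], np.ndarray] | None = None


def _briere1(p, t):
    """Brière-1 development rate: a·T·(T−Tmin)·sqrt(Tmax−T), zero outside."""
    t = np.asarray(t, dtype=float)
    lo, hi = p["t_min"], p["t_max"]
    inside = (t > lo) & (t < hi)
    r = np.zeros_like(t)
    ti = t[inside]
    r[inside] = p["a"] * ti * (ti - lo) * np.sqrt(hi - ti)
    return np.maximum(r, 0.0)


def _beta_rate(p, t):
    """Unimodal beta rate with explicit lower/upper limits and optimum."""
    t = np.asarray(t, dtype=float)
    lo, opt, hi = p["t_min"], p["t_opt"], p["t_max"]
    if not lo < opt < hi:
        raise ConfigurationError("beta rate requires t_min < t_opt < t_max")
    inside = (t > lo) & (t < hi)
    r = np.zeros_like(t)
    ti = t[inside]
    expo = (opt - lo) / (hi - opt)
    r[inside] = p["r_max"] * ((hi - ti) / (hi - opt)) * ((ti - lo) / (opt - lo)) ** expo
    return np.maximum(r, 0.0)


def _stress_hazard_q(p, t):
    """Cumulative hazard of the stress mortality model.

    An asymmetric quadratic hazard core centred on ``t_ref`` (chronic
    thermal stress, usually harsher on the cold side for tropical
    insects) plus sharp high-power heat and cold stress terms that switch
    on beyond ``t_hot`` / ``t_cold`` (acute lethality).
    """
    t = np.asarray(t, dtype=float)
    below = np.maximum(p["t_ref"] - t, 0.0)
    above = np.maximum(t - p["t_ref"], 0.0)
    q = p["c0"] + p["c_cold"] * below ** 2 + p["c_hot"] * above ** 2
    hot = np.maximum(t - p["t_hot"], 0.0) / p["w_hot"]
    cold = np.maximum(p["t_cold"] - t, 0.0) / p["w_cold"]
    with np.errstate(over="ignore"):
        q = q + hot ** p["p_hot"] + cold ** p["p_cold"]
    return q


def _stress_hazard_m(p, t):
    with np.errstate(over="ignore"):
        return -np.expm1(-_stress_hazard_q(p, t))


def _constant_mortality(p, t):
    t = np.asarray(t, dtype=float)
    m = float(p["m"])
    if not 0.0 <= m <= 1.0:
        raise ConfigurationError("constant mortality must lie in [0, 1]")
    return np.full_like(t, m)


def _constant_mortality_q(p, t):
    t = np.asarray(t, dtype=float)
    m = float(p["m"])
    q = np.inf if m >= 1.0 else -np.log1p(-m)
    return np.full_like(t, q)


def _gaussian_fecundity(p, t):
    t = np.asarray(t, dtype=float)
    z = (t - p["t_opt"]) / p["sigma"]
    return p["f_max"] * np.exp(-0.5 * z * z)


def _skew_gaussian_fecundity(p, t):
    """Asymmetric Gaussian with a low plateau (residual egg laying)."""
    t = np.asarray(t, dtype=float)
    sigma = np.where(t < p["t_opt"], p["sigma_left"], p["sigma_right"])
    z = (t - p["t_opt"]) / sigma
    f = p["f_floor"] + (p["f_max"] - p["f_floor"]) * np.exp(-0.5 * z * z)
    return np.maximum(f, 0.0)


def _exponential_senescence(p, t):
    t = np.asarray(t, dtype=float)
    return p["a"] * np.exp(p["b"] * t)


FAMILIES: Dict[str, Family] = {
    f.name: f
    for f in [
        Family(
            "briere1",
            frozenset({"development_rate"}),
            frozenset({"a", "t_min", "t_max"}),
            _briere1,
            optional=frozenset({"t_opt"}),
        ),
        Family(
            "beta",
            frozenset({"development_rate"}),
            frozenset({"r_max", "t_min", "t_opt", "t_max"}),
            _beta_rate,
        ),
        Family(
            "stress_hazard",
            frozenset({"immature_mortality"}),
            frozenset(
                {"t_ref", "c0", "c_cold", "c_hot", "t_hot", "w_hot", "p_hot",
                 "t_cold", "w_cold", "p_cold"}
            ),
            _stress_hazard_m,
            hazard=_stress_hazard_q,
        ),
        Family(
            "constant",
            frozenset({"immature_mortality"}),
            frozenset({"m"}),
            _constant_mortality,
            hazard=_constant_mortality_q,
        ),
        Family(
            "gaussian",
            frozenset({"fecundity"}),
            frozenset({"f_max", "t_opt", "sigma"}),
            _gaussian_fecundity,
        ),
        Family(
            "skew_gaussian",
            frozenset({"fecundity"}),
            frozenset({"f_max", "f_floor", "t_opt", "sigma_left", "sigma_right"}),
            _skew_gaussian_fecundity,
        ),
        Family(
            "exponential",
            frozenset({"senescence_rate"}),
            frozenset({"a", "b"}),
            _exponential_senescence,
        ),
    ]
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown response family {name!r}; known: {sorted(FAMILIES)}"
        ) from None
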