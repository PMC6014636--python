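"""Statistics for the farm survey and the current-vs-future comparison.

Counts of bugs per farm (totals over 15 trees) are regressed on elevation
or season with a log-link Poisson GLM.  Count data of this kind are
routinely overdispersed; the fit is corrected with an iterative
weighted-likelihood scheme: fit, estimate the dispersion from the Pearson
statistic, downweight every observation by the reciprocal dispersion,
refit, and repeat until the dispersion estimate stabilises at 1.  The
coefficients are those of the plain Poisson fit; standard errors and the
goodness-of-fit deviance absorb the extra-Poisson variation.

Current-vs-future risk-index changes are tested per elevation band with a
paired Wilcoxon signed-rank test (exact null distribution up to n = 25).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, studentized_range

__all__ = [
    "SEASONS",
    "GLMFit",
    "WilcoxonResult",
    "fit_overdispersed_poisson",
    "season_posthoc",
    "wilcoxon_signed_rank",
    "compare_bands",
    "read_survey_csv",
    "significance_stars",
]

SEASONS = ("cool-dry-2014", "short-rainy-2014", "warm-dry-2015", "cool-dry-2015")

MAX_DISPERSION_ITER = 100
DISPERSION_TOL = 1e-8


class FitError(RuntimeError):
    """GLM failed to converge or the design is unusable."""


@dataclass(frozen=True)
class GLMFit:
    """An overdispersion-corrected Poisson regression fit (log link)."""

    predictor: str                  # "elevation" or "season"
    term_names: Tuple[str, ...]
    params: np.ndarray              # coefficient estimates
    bse: np.ndarray                 # standard errors (dispersion-corrected)
    dispersion: float               # >= 1 after the correction loop
    deviance: float                 # goodness-of-fit chi-square
    df_resid: int
    fitted: np.ndarray
    weights: np.ndarray             # final prior weights (1/dispersion)
    cov: np.ndarray
    n_iter: int

    @property
    def z(self) -> np.ndarray:
        """Per-coefficient z statistics, estimate / SE."""
        return self.params / self.bse

    def summary_dict(self) -> Dict[str, float]:
        out = {"chi2": self.deviance, "df": self.df_resid,
               "dispersion": self.dispersion}
        for name, b, se, z in zip(self.term_names, self.params, self.bse, self.z):
            out[f"coef[{name}]"] = float(b)
            out[f"se[{name}]"] = float(se)
            out[f"z[{name}]"] = float(z)
        return out


def _design(surveys: pd.DataFrame, predictor: str):
    if predictor == "elevation":
        x = surveys["elevation_m"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise FitError("elevation has zero variance; cannot fit a slope")
        X = np.column_stack([np.ones_like(x), x])
        names = ("intercept", "elevation")
    elif predictor == "season":
        seasons = pd.Categorical(surveys["season"])
        if len(seasons.categories) < 2:
            raise ValueError("need at least 2 seasons for the season model")
        dummies = pd.get_dummies(seasons, drop_first=True).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(surveys)), dummies])
        names = ("intercept",) + tuple(str(c) for c in seasons.categories[1:])
    else:
        raise ValueError(f"unsupported predictor {predictor!r}")
    return X, names


def fit_overdispersed_poisson(surveys: pd.DataFrame, formula: str) -> GLMFit:
    """Fit ``count ~ elevation`` or ``count ~ season`` with dispersion
    correction.

    Parameters
    ----------
    surveys : DataFrame
        One row per farm (and season, for the season model) with columns
        ``count`` plus ``elevation_m`` or ``season``.
    formula : str
        ``"count ~ elevation"`` or ``"count ~ season"``.
    """
    lhs, _, rhs = [s.strip() for s in formula.partition("~")]
    if lhs != "count" or rhs not in ("elevation", "season"):
        raise ValueError(f"unsupported formula {formula!r}")
    y = surveys["count"].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    X, names = _design(surveys, rhs)
    if len(y) <= X.shape[1]:
        raise FitError("more coefficients than observations")

    df_resid = len(y) - X.shape[1]
    total_dispersion = 1.0
    res = None
    for iteration in range(1, MAX_DISPERSION_ITER + 1):
        weights = np.full_like(y, 1.0 / total_dispersion)
        model = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=weights)
        res = model.fit(scale=1.0)
        phi = float(res.pearson_chi2) / df_resid
        if abs(phi - 1.0) < DISPERSION_TOL:
            break
        # downweight by the reciprocal of the remaining dispersion, never
        # inflating the likelihood of under-dispersed data
        new_total = max(total_dispersion * phi, 1.0)
        if new_total == total_dispersion:
            break
        total_dispersion = new_total
    else:
        raise FitError(
            f"dispersion correction did not converge in {MAX_DISPERSION_ITER} iterations"
        )

    return GLMFit(
        predictor=rhs,
        term_names=names,
        params=np.asarray(res.params, dtype=float),
        bse=np.asarray(res.bse, dtype=float),
        dispersion=max(total_dispersion, 1.0),
        deviance=float(res.deviance),
        df_resid=len(y) - X.shape[1],
        fitted=np.asarray(res.fittedvalues, dtype=float),
        weights=weights,
        cov=np.asarray(res.cov_params(), dtype=float),
        n_iter=iteration,
    )


def season_posthoc(fit: GLMFit, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise season contrasts on the linear-predictor scale.

    Single-step adjustment through the studentized range distribution
    (the Tukey analogue for a GLM); adjusted p-values are never smaller
    than the unadjusted normal-theory p-values.
    """
    if fit.predictor != "season":
        raise ValueError("post hoc comparisons need a season-model fit")
    k = len(fit.term_names)  # intercept + (k-1) season contrasts
    if k < 2:
        raise ValueError("need at least 2 seasons")
    # linear predictor per season: intercept is the reference season
    names = ["<reference>"] + list(fit.term_names[1:])
    names[0] = _reference_season_name(fit)
    L = np.zeros((k, k))
    L[:, 0] = 1.0
    for i in range(1, k):
        L[i, i] = 1.0
    means = L @ fit.params
    cov = L @ fit.cov @ L.T

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        se = math.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j])
        q = abs(diff) / se * math.sqrt(2.0)
        p_unadj = 2.0 * norm.sf(abs(diff) / se)
        p_adj = float(studentized_range.sf(q, k, max(fit.df_resid, 1)))
        p_adj = min(max(p_adj, p_unadj), 1.0)
        rows.append({
            "season_a": names[i], "season_b": names[j],
            "difference": float(diff), "se": float(se),
            "p_unadjusted": float(min(p_unadj, 1.0)),
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        })
    return pd.DataFrame(rows)


def _reference_season_name(fit: GLMFit) -> str:
    contrasts = set(fit.term_names[1:])
    for s in SEASONS:
        if s not in contrasts:
            return s
    return "reference"


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass(frozen=True)
class WilcoxonResult:
    """Paired signed-rank test result (W = rank sum of positive diffs)."""

    statistic: float
    p_value: float
    n: int
    exact: bool

    def __post_init__(self):
        if not 0.0 <= self.statistic <= self.n * (self.n + 1) / 2:
            raise ValueError("W outside [0, n(n+1)/2]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value outside (0, 1]")


def _exact_signed_rank_p(double_ranks: np.ndarray, double_w: int) -> float:
    """Two-sided exact p by dynamic programming over sign assignments.

    Works on ranks doubled to integers so tied (half-integer) average
    ranks are handled exactly.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    counts /= counts.sum()
    lower = counts[: double_w + 1].sum()
    upper = counts[double_w:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(current: Sequence[float], future: Sequence[float],
                         exact_limit: int = 25) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on ``future − current``.

    Zero differences are dropped; ties receive average ranks.  The exact
    null distribution is enumerated for n ≤ ``exact_limit``; otherwise a
    normal approximation with tie-corrected variance and continuity
    correction is used.
    """
    cur = np.asarray(current, dtype=float)
    fut = np.asarray(future, dtype=float)
    if cur.shape != fut.shape:
        raise ValueError("current and future must have the same length")
    d = fut - cur
    d = d[d != 0.0]
    n = d.size
    if n < 5:
        raise ValueError(f"only {n} non-zero paired differences; need >= 5")

    order = np.abs(d)
    ranks = pd.Series(order).rank(method="average").to_numpy()
    w_pos = float(ranks[d > 0].sum())

    if n <= exact_limit:
        double_ranks = np.round(2 * ranks).astype(int)
        p = _exact_signed_rank_p(double_ranks, int(round(2 * w_pos)))
        return WilcoxonResult(statistic=w_pos, p_value=p, n=n, exact=True)

    mean = ranks.sum() / 2.0
    var = float(np.sum(ranks ** 2)) / 4.0
    z = (w_pos - mean - np.sign(w_pos - mean) * 0.5) / math.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_pos, p_value=max(p, np.finfo(float).tiny),
                          n=n, exact=False)


def significance_stars(p: float) -> str:
    """Figure-style significance stars: * <0.05, ** <0.001, *** <0.0001."""
    if p < 0.0001:
        return "***"
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_bands(
    points: pd.DataFrame,
    index_names: Sequence[str] = ("eri", "gi", "ai"),
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Per-band, per-index paired Wilcoxon tests of future vs current.

    ``points`` is the table from :func:`antestia.spatial_mapping.band_sample`
    with paired columns ``{index}_current`` and ``{index}_future``.  Bands
    with fewer than ``min_pairs`` usable pairs are skipped with a warning.
    """
    rows = []
    for band, grp in points.groupby("band_m", sort=True):
        for name in index_names:
            cur = grp[f"{name}_current"].to_numpy(dtype=float)
            fut = grp[f"{name}_future"].to_numpy(dtype=float)
            keep = np.isfinite(cur) & np.isfinite(fut)
            cur, fut = cur[keep], fut[keep]
            usable = int(np.sum((fut - cur) != 0))
            if usable < min_pairs:
                warnings.warn(
                    f"band {band:g} m, index {name}: only {usable} usable "
                    "pairs; skipped", stacklevel=2,
                )
                continue
            res = wilcoxon_signed_rank(cur, fut)
            med = float(np.median(fut - cur))
            rows.append({
                "band_m": float(band), "index": name,
                "W": res.statistic, "p_value": res.p_value, "n": res.n,
                "exact": res.exact,
                "direction": int(np.sign(med)),
                "median_change": med,
                "stars": significance_stars(res.p_value),
            })
    return pd.DataFrame(rows)


def read_survey_csv(path) -> pd.DataFrame:
    """Load a farm survey CSV and aggregate per-tree counts to farm totals.

    Accepts either per-tree rows (``tree_index``/``count``) or pre-summed
    farm totals; returns one row per farm × season with columns
    ``farm_id``, ``lon``, ``lat``, ``elevation_m``, ``season``, ``count``.
    """
    df = pd.read_csv(path)
    required = {"farm_id", "elevation_m", "season", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    keys = [c for c in ("farm_id", "lon", "lat", "elevation_m", "season") if c in df.columns]
    if "tree_index" in df.columns:
        df = df.groupby(keys, as_index=False)["count"].sum()
    if np.any(df["count"] < 0) or np.any(df["count"] != np.round(df["count"])):
        raise ValueError("counts must be non-negative integers")
    return df
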