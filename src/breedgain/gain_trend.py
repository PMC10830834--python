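"""Genetic-trend estimation.

Linear genetic gain is the OLS slope of breeding values on the year of
origin (year the cross was made), the year of testing, or the year of
release, converted to percent per annum against a named baseline.  A
tricube-weighted local polynomial (loess) curve shows non-linear short- and
long-term trends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("breedgain")

BASELINE_RULES = ("mean_of_values", "fitted_at_first_year")
REGRESSORS = ("year_of_origin", "year_of_testing", "year_of_release")


class InsufficientDataError(ValueError):
    pass


@dataclass
class TrendResult:
    slope: float               # kg/ha per year
    slope_se: float
    intercept: float
    percent_per_annum: float   # 100 * slope / baseline
    baseline: float
    baseline_rule: str
    n: int
    regressor: str
    loess_curve: Optional[pd.DataFrame] = None  # year, fitted

    def to_dict(self) -> dict:
        return {
            "slope_kg_ha_per_year": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "percent_per_annum": self.percent_per_annum,
            "baseline_kg_ha": self.baseline,
            "baseline_rule": self.baseline_rule,
            "n_genotypes": self.n,
            "regressor": self.regressor,
        }


def _align(values, years):
    v = pd.Series(values, dtype=float)
    y = pd.Series(years, dtype=float)
    joined = pd.concat({"value": v, "year": y}, axis=1).dropna()
    return joined["value"].to_numpy(), joined["year"].to_numpy()


def fit_linear_trend(values, years, baseline_rule: str = "mean_of_values",
                     regressor: str = "year_of_origin",
                     weights=None) -> TrendResult:
    """OLS of breeding value on year, with percent-per-annum conversion.

    ``values`` and ``years`` are genotype-indexed mappings/Series; only
    genotypes present in both enter.  ``weights`` (optional, e.g.
    reliabilities) switches to weighted least squares.  The percent rate
    divides the slope by either the mean of the values (default) or the
    fitted value at the first year.
    """
    if baseline_rule not in BASELINE_RULES:
        raise ValueError(f"baseline_rule must be one of {BASELINE_RULES}")
    v, y = _align(values, years)
    n = len(v)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 genotypes with value and year, got {n}")
    if np.ptp(y) == 0:
        raise InsufficientDataError("all years identical; slope undefined")
    if weights is None:
        res = stats.linregress(y, v)
        slope, intercept, se = float(res.slope), float(res.intercept), float(res.stderr)
    else:
        w = pd.Series(weights, dtype=float)
        joined = pd.concat({"value": pd.Series(values, dtype=float),
                            "year": pd.Series(years, dtype=float),
                            "w": w}, axis=1).dropna()
        v = joined["value"].to_numpy()
        y = joined["year"].to_numpy()
        w = joined["w"].to_numpy()
        n = len(v)
        X = np.column_stack([np.ones(n), y])
        XtWX = X.T @ (w[:, None] * X)
        beta = np.linalg.solve(XtWX, X.T @ (w * v))
        resid = v - X @ beta
        s2 = float(resid @ (w * resid)) / (n - 2)
        cov = s2 * np.linalg.inv(XtWX)
        intercept, slope = float(beta[0]), float(beta[1])
        se = float(np.sqrt(cov[1, 1]))
    if baseline_rule == "mean_of_values":
        baseline = float(np.mean(v))
    else:
        baseline = float(intercept + slope * np.min(y))
    percent = 100.0 * slope / baseline if baseline != 0 else float("nan")
    return TrendResult(slope=slope, slope_se=se, intercept=intercept,
                       percent_per_annum=percent, baseline=baseline,
                       baseline_rule=baseline_rule, n=n, regressor=regressor)


def fit_loess_trend(values, years, span: float = 0.75,
                    degree: int = 2) -> pd.DataFrame:
    """Tricube-weighted local polynomial fit on the observed year grid.

    Deterministic; ties in year are allowed and each distinct year gets one
    fitted value.  The window holds the ``ceil(span * n)`` nearest points;
    a window smaller than degree + 2 points raises an error naming the
    first affected year.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    v, y = _align(values, years)
    n = len(v)
    if n < 10:
        raise InsufficientDataError(f"loess needs >= 10 points, got {n}")
    k = int(np.ceil(span * n))
    grid = np.unique(y)
    fitted = []
    for x0 in grid:
        d = np.abs(y - x0)
        order = np.argsort(d, kind="stable")
        idx = order[:k]
        # include ties with the last admitted distance
        dmax = d[idx].max()
        idx = np.flatnonzero(d <= dmax)
        if len(np.unique(y[idx])) < degree + 1 or len(idx) < degree + 2:
            raise InsufficientDataError(
                f"loess window at year {x0:g} has too few points for degree {degree}")
        if dmax == 0:
            w = np.ones(len(idx))
        else:
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3
            w = np.clip(w, 1e-12, None)
        coeffs = np.polynomial.polynomial.polyfit(
            y[idx] - x0, v[idx], deg=degree, w=np.sqrt(w))
        fitted.append(coeffs[0])
    return pd.DataFrame({"year": grid, "fitted": np.asarray(fitted, dtype=float)})


def trend_analysis(values, years, baseline_rule: str = "mean_of_values",
                   regressor: str = "year_of_origin", span: float = 0.75,
                   degree: int = 2, weights=None) -> TrendResult:
    """Linear trend plus (when enough points) the loess curve."""
    result = fit_linear_trend(values, years, baseline_rule=baseline_rule,
                              regressor=regressor, weights=weights)
    v, y = _align(values, years)
    if len(v) >= 10:
        try:
            result.loess_curve = fit_loess_trend(values, years, span=span,
                                                 degree=degree)
        except InsufficientDataError as exc:
            logger.warning("loess curve skipped: %s", exc)
    return result


def released_variety_trend(stage2_table: pd.DataFrame, releases,
                           baseline_rule: str = "mean_of_values") -> TrendResult:
    """Genetic gain of released varieties: BVs regressed on year of release.

    ``releases`` maps genotype -> release year; only released genotypes with
    a breeding value enter.
    """
    rel = pd.Series(releases, dtype=float).dropna()
    if rel.empty:
        raise InsufficientDataError("no released genotypes supplied")
    bv = stage2_table.set_index("genotype")["breeding_value"]
    common = [g for g in rel.index if g in bv.index]
    if len(common) < 3:
        raise InsufficientDataError(
            f"need >= 3 released genotypes with breeding values, got {len(common)}")
    return fit_linear_trend(bv.loc[common], rel.loc[common],
                            baseline_rule=baseline_rule,
                            regressor="year_of_release")
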