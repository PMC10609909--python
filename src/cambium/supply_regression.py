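"""Seasonal inhibitor-supply regression.

The supply of growth inhibitor deposited in the initial cell at the start of
a growing season is predicted from the distribution of that season's daily
integral growth rates (sd, median, mad, min, max) plus the skewness of the
*previous* season's distribution — the previous season enters only through
its asymmetry, a proxy for the reserves spent resisting stress the year
before.  The default coefficients are the published least-squares fit on
Siberian larch; :func:`fit_supply_regression` refits them from per-season
training pairs by ordinary least squares.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm

from .env_series import SummaryStats

#: Order of regressors in the design matrix (after the intercept).
REGRESSOR_NAMES = ("sd", "median", "mad", "min", "max", "skew_prev")


@dataclass
class SupplyRegression:
    """Linear model for the seasonal inhibitor supply.

    supply = intercept + beta_sd*sd + beta_median*median + beta_mad*mad
             + beta_min*min + beta_max*max + beta_skew_prev*skew(prev season)

    Defaults are the published coefficients.
    """

    intercept: float = 1.184
    beta_sd: float = 9.44
    beta_median: float = 2.0209
    beta_mad: float = -3.4693
    beta_min: float = -16.5541
    beta_max: float = -1.4214
    beta_skew_prev: float = -0.3408

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not np.isfinite(value):
                raise ValueError(f"coefficient {name} must be finite")

    @property
    def coefficients(self) -> np.ndarray:
        """Intercept followed by the betas in :data:`REGRESSOR_NAMES` order."""
        return np.array(
            [
                self.intercept, self.beta_sd, self.beta_median, self.beta_mad,
                self.beta_min, self.beta_max, self.beta_skew_prev,
            ]
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SupplyRegression":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


class SupplyPrediction(NamedTuple):
    """Predicted supply plus a flag marking nonphysical (≤ 0) values.

    A nonpositive supply is returned unchanged — the season simulator decides
    what to do with it (it treats any supply at or below C_min·D_init as
    "no growth possible").
    """

    value: float
    nonpositive: bool


def predict_supply(
    stats_current: SummaryStats,
    skew_previous: float,
    model: SupplyRegression | None = None,
) -> SupplyPrediction:
    """Evaluate the supply regression for one season."""
    if model is None:
        model = SupplyRegression()
    x = np.array(
        [
            1.0, stats_current.sd, stats_current.median, stats_current.mad,
            stats_current.min, stats_current.max, skew_previous,
        ]
    )
    value = float(x @ model.coefficients)
    return SupplyPrediction(value=value, nonpositive=value <= 0.0)


@dataclass
class SupplyFit:
    """Result of refitting the supply regression by OLS."""

    model: SupplyRegression
    stderr: np.ndarray          # intercept first, then betas
    fitted: np.ndarray
    residuals: np.ndarray
    r_squared: float
    nobs: int


def fit_supply_regression(
    samples: Sequence[tuple[SummaryStats, float, float]],
) -> SupplyFit:
    """Fit the 6-regressor supply model by ordinary least squares.

    ``samples`` holds per-season triples ``(stats_current, skew_previous,
    target_supply)``.  At least 7 seasons (one per free coefficient) with a
    full-rank design are required.
    """
    n = len(samples)
    if n < 7:
        raise ValueError(
            f"need at least 7 seasons to fit 7 coefficients, got {n}"
        )
    X = np.empty((n, 7))
    y = np.empty(n)
    for i, (stats, skew_prev, target) in enumerate(samples):
        X[i] = (
            1.0, stats.sd, stats.median, stats.mad, stats.min, stats.max,
            skew_prev,
        )
        y[i] = target
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient design matrix: regressors are "
                         "collinear across the supplied seasons")
    res = sm.OLS(y, X).fit()
    coef = res.params
    model = SupplyRegression(
        intercept=coef[0], beta_sd=coef[1], beta_median=coef[2],
        beta_mad=coef[3], beta_min=coef[4], beta_max=coef[5],
        beta_skew_prev=coef[6],
    )
    return SupplyFit(
        model=model,
        stderr=np.asarray(res.bse),
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
        r_squared=float(res.rsquared),
        nobs=n,
    )
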