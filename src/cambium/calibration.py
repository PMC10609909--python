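"""Multi-year calibration and verification harness.

Workflow: infer the per-season inhibitor supply that reproduces an observed
annual cell count (monotone bisection through the season simulator), refit
the seasonal supply regression from per-season training pairs, run the
simulator over a record of years with regression-predicted supplies, score
calibration/verification splits, tune invariant parameters on an "average
growth season", and filter unusable seasons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import pearsonr

from .cell_cycle import ParameterSet
from .env_series import DailyGrowthSeries, season_stats
from .season_sim import SeasonResult, simulate_season
from .supply_regression import (
    SupplyFit,
    SupplyRegression,
    fit_supply_regression,
    predict_supply,
)


@dataclass(frozen=True)
class StudyRecord:
    """A multi-year study: observed production, exclusions and split."""

    years: tuple[int, ...]
    observed_production: Mapping[int, float]
    excluded_years: Mapping[int, str] = field(default_factory=dict)
    calibration_years: tuple[int, ...] = ()
    verification_years: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", tuple(self.years))
        object.__setattr__(
            self, "observed_production", dict(self.observed_production)
        )
        object.__setattr__(self, "excluded_years", dict(self.excluded_years))
        object.__setattr__(
            self, "calibration_years", tuple(self.calibration_years)
        )
        object.__setattr__(
            self, "verification_years", tuple(self.verification_years)
        )
        for year in self.excluded_years:
            if (
                year in self.calibration_years
                or year in self.verification_years
            ):
                raise ValueError(
                    f"excluded year {year} still present in a split set"
                )
        for year, cells in self.observed_production.items():
            if cells < 0:
                raise ValueError(
                    f"observed production for {year} is negative ({cells})"
                )


def load_exclusion_mask(path) -> dict[int, str]:
    """Load a year -> reason exclusion mask from a YAML or JSON file."""
    import json

    import yaml

    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    data = (
        json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    )
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a mapping of year -> reason")
    return {int(year): str(reason) for year, reason in data.items()}


def load_observed_production(path) -> dict[int, float]:
    """Load an observed annual cell-production CSV (``year,cells``)."""
    df = pd.read_csv(path)
    missing = {"year", "cells"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return {int(r.year): float(r.cells) for r in df.itertuples()}


class SupplyInference(NamedTuple):
    """Result of inverting the simulator for a target production."""

    supply: float
    production: int
    attained: bool


def infer_supply_for_production(
    series: DailyGrowthSeries,
    params: ParameterSet,
    target: float,
    *,
    rel_tol: float = 1e-4,
    max_doublings: int = 40,
) -> SupplyInference:
    """Smallest supply whose simulated production reaches ``target`` cells.

    Uses the monotone trend of production in supply: the upper bracket is
    doubled until production reaches the target (or visibly plateaus below
    it — a short season cannot produce arbitrarily many cells, in which case
    the closest-production supply is returned with ``attained=False``), then
    the smallest sufficient supply is located by bisection to ``rel_tol``
    relative precision.
    """
    if not math.isfinite(target):
        raise ValueError(f"target production must be finite, got {target}")
    if target <= 0:
        return SupplyInference(supply=0.0, production=0, attained=True)

    def production_at(s: float) -> int:
        return simulate_season(series, params, s).production

    lo, lo_prod = 0.0, 0
    hi = 1.0
    hi_prod = production_at(hi)
    best = (abs(hi_prod - target), hi, hi_prod)
    stall = 0
    while hi_prod < target:
        lo, lo_prod = hi, hi_prod
        hi *= 2.0
        prev = hi_prod
        hi_prod = production_at(hi)
        if abs(hi_prod - target) < best[0]:
            best = (abs(hi_prod - target), hi, hi_prod)
        stall = stall + 1 if hi_prod <= prev else 0
        if stall >= 6 or hi > 2.0**max_doublings:
            return SupplyInference(
                supply=best[1], production=best[2], attained=False
            )
    # smallest supply with production >= target
    while hi - lo > rel_tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        mid_prod = production_at(mid)
        if mid_prod >= target:
            hi, hi_prod = mid, mid_prod
        else:
            lo, lo_prod = mid, mid_prod
    attained = hi_prod == int(target)
    if not attained and abs(lo_prod - target) < abs(hi_prod - target):
        return SupplyInference(supply=lo, production=lo_prod, attained=False)
    return SupplyInference(supply=hi, production=hi_prod, attained=attained)


def skew_prev_for_year(
    series_by_year: Mapping[int, DailyGrowthSeries],
    year: int,
    default: float = 0.0,
) -> float:
    """Skewness of the previous season's rates, or ``default`` if absent."""
    prev = series_by_year.get(year - 1)
    if prev is None:
        warnings.warn(
            f"no previous season for {year}; using default skew {default}",
            stacklevel=2,
        )
        return default
    return season_stats(prev).skew


def run_multi_year(
    series_by_year: Mapping[int, DailyGrowthSeries],
    params: ParameterSet,
    model: SupplyRegression | None = None,
    *,
    skew_prev_default: float = 0.0,
    supplies: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Simulate every year of a record with regression-predicted supplies.

    If ``supplies`` is given those values are used directly (e.g. fixture
    truth or manually inferred supplies); otherwise each year's supply is
    predicted from its growth-rate statistics and the previous year's
    skewness (``skew_prev_default`` when the predecessor is missing).
    Returns one summary row per year.
    """
    if model is None:
        model = SupplyRegression()
    rows = []
    for year in sorted(series_by_year):
        series = series_by_year[year]
        if supplies is not None:
            supply, flagged = float(supplies[year]), supplies[year] <= 0.0
        else:
            stats = season_stats(series)
            skew_prev = skew_prev_for_year(
                series_by_year, year, skew_prev_default
            )
            supply, flagged = predict_supply(stats, skew_prev, model)
            if flagged:
                warnings.warn(
                    f"year {year}: nonpositive predicted supply "
                    f"{supply:.4f}; production will be 0",
                    stacklevel=2,
                )
        result = simulate_season(series, params, supply)
        rows.append(
            {
                "year": year,
                "supply": supply,
                "nonpositive_supply": flagged,
                "production": result.production,
                "n_divisions": result.n_divisions,
                "simulated_season_length": result.simulated_season_length,
                "env_season_length": result.env_season_length,
                "termination_reason": result.termination_reason,
            }
        )
    return pd.DataFrame(rows)


def _r_squared(x: np.ndarray, y: np.ndarray, label: str) -> float:
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError(
            f"{label}: constant series, correlation undefined"
        )
    r = float(pearsonr(x, y)[0])
    return r * r


def split_goodness(
    observed: Mapping[int, float],
    simulated: Mapping[int, float],
    split: StudyRecord | tuple[Iterable[int], Iterable[int]],
) -> dict[str, float]:
    """Goodness-of-fit of simulated vs observed production per split period.

    The coefficient of determination is the squared Pearson correlation
    between observed and simulated values within each period; the overall
    Pearson r spans both periods.
    """
    if isinstance(split, StudyRecord):
        cal_years: Sequence[int] = split.calibration_years
        ver_years: Sequence[int] = split.verification_years
    else:
        cal_years, ver_years = (tuple(s) for s in split)
    out: dict[str, float] = {}
    for label, years in (
        ("calibration", cal_years), ("verification", ver_years)
    ):
        years = [y for y in years if y in observed and y in simulated]
        if len(years) < 3:
            raise ValueError(
                f"{label} period needs at least 3 usable years, got "
                f"{len(years)}"
            )
        obs = np.array([observed[y] for y in years], dtype=float)
        sim = np.array([simulated[y] for y in years], dtype=float)
        out[f"R2_{label}"] = _r_squared(obs, sim, label)
    all_years = sorted(set(cal_years) | set(ver_years))
    all_years = [y for y in all_years if y in observed and y in simulated]
    obs = np.array([observed[y] for y in all_years], dtype=float)
    sim = np.array([simulated[y] for y in all_years], dtype=float)
    if np.ptp(obs) == 0.0 or np.ptp(sim) == 0.0:
        raise ValueError("overall: constant series, correlation undefined")
    out["r_overall"] = float(pearsonr(obs, sim)[0])
    return out


@dataclass
class CalibrationResult:
    params: ParameterSet
    supply: float
    objective: float
    trace: list[tuple[dict, float]]


def calibrate_average_season(
    avg: DailyGrowthSeries,
    params: ParameterSet,
    targets: Mapping[str, float],
    free_params: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    *,
    supply: float | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
    n_grid: int = 17,
) -> CalibrationResult:
    """Tune a subset of parameters against average-season targets.

    ``targets`` may contain ``production`` (cells) and/or
    ``first_division_day`` (days from season start).  ``free_params`` names
    ParameterSet fields, plus the pseudo-parameter ``supply``; every free
    parameter needs finite ``bounds``.  The objective is the weighted sum of
    squared target misses.  Minimisation is derivative-free: a deterministic
    bounded start grid (the production response is a step function, so local
    moves alone can stall on a plateau) followed by Nelder–Mead polish from
    the best start.  If the initial configuration already meets the targets
    it is returned unchanged.
    """
    free = list(free_params)
    if not free:
        raise ValueError("free_params must not be empty")
    if not targets:
        raise ValueError("targets must not be empty")
    for name in free:
        if name not in bounds:
            raise ValueError(f"no bounds given for free parameter {name!r}")
        lo, hi = bounds[name]
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError(f"bounds for {name!r} must be finite with lo < hi")
    if "supply" not in free and supply is None:
        raise ValueError("fixed supply value required when not calibrated")

    w_prod, w_day = weights
    trace: list[tuple[dict, float]] = []

    def build(x: np.ndarray) -> tuple[ParameterSet, float]:
        changes = {
            name: float(v) for name, v in zip(free, x) if name != "supply"
        }
        p = replace(params, **changes) if changes else params
        s = float(x[free.index("supply")]) if "supply" in free else supply
        return p, s

    def objective(x: np.ndarray) -> float:
        try:
            p, s = build(x)
        except ValueError:
            return float("inf")
        res: SeasonResult = simulate_season(avg, p, s)
        obj = 0.0
        if "production" in targets:
            obj += w_prod * (res.production - targets["production"]) ** 2
        if "first_division_day" in targets:
            fd = res.first_division_time
            if math.isnan(fd):
                fd = float(res.env_season_length)
            obj += w_day * (fd - targets["first_division_day"]) ** 2
        trace.append(({n: float(v) for n, v in zip(free, x)}, obj))
        return obj

    x0 = np.array(
        [
            (
                0.5 * (bounds[name][0] + bounds[name][1])
                if supply is None
                else supply
            )
            if name == "supply"
            else getattr(params, name)
            for name in free
        ],
        dtype=float,
    )
    f0 = objective(x0)
    if f0 <= 1e-12:
        p, s = build(x0)
        return CalibrationResult(params=p, supply=s, objective=f0, trace=trace)

    axes = [
        np.linspace(*bounds[name], n_grid if len(free) == 1 else 5)
        for name in free
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    candidates = np.stack([g.ravel() for g in grids], axis=-1)
    best_x, best_f = x0, f0
    for x in candidates:
        f = objective(x)
        if f < best_f:
            best_x, best_f = x, f
    if not math.isfinite(best_f):
        raise ValueError("objective non-finite at every start point")

    res = minimize(
        objective,
        best_x,
        method="Nelder-Mead",
        bounds=[bounds[name] for name in free],
        options={"xatol": 1e-6, "fatol": 1e-12, "maxfev": 400},
    )
    x_best, f_best = (
        (res.x, float(res.fun)) if res.fun <= best_f else (best_x, best_f)
    )
    p, s = build(np.asarray(x_best, dtype=float))
    return CalibrationResult(params=p, supply=s, objective=f_best, trace=trace)


def filter_seasons(
    record: StudyRecord, mask: Mapping[int, str]
) -> StudyRecord:
    """Exclude masked years (with reasons) from a study record.

    The discrepancy criterion itself is the user's: seasons whose simulated
    and observed growth disagree badly enough to suggest corrupt inputs are
    named explicitly in ``mask``.
    """
    for year in mask:
        if year not in record.years:
            raise ValueError(f"mask names unknown year {year}")
    excluded = dict(record.excluded_years)
    excluded.update({int(y): str(reason) for y, reason in mask.items()})
    keep = lambda ys: tuple(y for y in ys if y not in mask)  # noqa: E731
    return StudyRecord(
        years=record.years,
        observed_production={
            y: c for y, c in record.observed_production.items() if y not in mask
        },
        excluded_years=excluded,
        calibration_years=keep(record.calibration_years),
        verification_years=keep(record.verification_years),
    )


@dataclass
class RecoveryReport:
    """Two-step verification of the automatic supply pipeline."""

    fit: SupplyFit
    predicted_supplies: dict[int, float]
    simulated_production: dict[int, int]
    supply_r2: float
    production_r2: float


def two_step_recovery(
    series_by_year: Mapping[int, DailyGrowthSeries],
    supplies_by_year: Mapping[int, float],
    params: ParameterSet,
    *,
    reference_supplies: Mapping[int, float] | None = None,
    observed_production: Mapping[int, float] | None = None,
    skew_prev_default: float = 0.0,
) -> RecoveryReport:
    """Refit the supply regression and verify it in two steps.

    Step 1 refits the regression on per-season (statistics, supply) pairs
    and scores its predictions against ``reference_supplies`` (defaults to
    the training supplies).  Step 2 simulates every season with the
    predicted supplies and scores production against
    ``observed_production`` (when given).  Both scores are squared Pearson
    correlations.
    """
    years = sorted(set(series_by_year) & set(supplies_by_year))
    samples = []
    for year in years:
        stats = season_stats(series_by_year[year])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            skew_prev = skew_prev_for_year(
                series_by_year, year, skew_prev_default
            )
        samples.append((stats, skew_prev, float(supplies_by_year[year])))
    fit = fit_supply_regression(samples)
    predicted = {
        year: float(fit.fitted[i]) for i, year in enumerate(years)
    }
    reference = (
        dict(supplies_by_year) if reference_supplies is None
        else dict(reference_supplies)
    )
    ref = np.array([reference[y] for y in years])
    pred = np.array([predicted[y] for y in years])
    supply_r2 = _r_squared(ref, pred, "supply recovery")

    simulated = {
        year: simulate_season(
            series_by_year[year], params, predicted[year]
        ).production
        for year in years
    }
    production_r2 = float("nan")
    if observed_production is not None:
        obs = np.array([observed_production[y] for y in years], dtype=float)
        sim = np.array([simulated[y] for y in years], dtype=float)
        production_r2 = _r_squared(obs, sim, "production recovery")
    return RecoveryReport(
        fit=fit,
        predicted_supplies=predicted,
        simulated_production=simulated,
        supply_r2=supply_r2,
        production_r2=production_r2,
    )
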