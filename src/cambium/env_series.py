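"""Daily integral growth-rate series for growing seasons.

The simulator is forced by one number per day: the integral growth rate
Gr(t) in [0, 1], the environmental multiplier produced upstream from daily
temperature, precipitation and photoperiod (the minimum of the partial
limiting-factor rates).  This module loads such series from CSV, summarises
a season's rate distribution (the regressors of the seasonal inhibitor-supply
regression), scans for multi-day climatic stress windows, and builds the
"average growth season" used for parameter calibration.

Day indexing: DOY is the 1-based calendar day; time *within* a season is
measured in days from ``doy_start`` with t = 0 at season start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps


class GrowthSeriesError(ValueError):
    """Raised for malformed growth-rate input (bad bounds, gaps, range)."""


@dataclass(frozen=True)
class DailyGrowthSeries:
    """One growing season of daily integral growth rates.

    Parameters
    ----------
    year : int
        Calendar year the season belongs to.
    doy_start, doy_end : int
        First and last day-of-year of the season (inclusive, 1-based).
    rates : numpy.ndarray
        Daily rates Gr(t) in [0, 1], one per day from ``doy_start`` to
        ``doy_end`` inclusive.
    """

    year: int
    doy_start: int
    doy_end: int
    rates: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        if self.doy_start >= self.doy_end:
            raise GrowthSeriesError(
                f"year {self.year}: doy_start ({self.doy_start}) must be < "
                f"doy_end ({self.doy_end})"
            )
        expected = self.doy_end - self.doy_start + 1
        if rates.ndim != 1 or len(rates) != expected:
            raise GrowthSeriesError(
                f"year {self.year}: expected {expected} daily rates for "
                f"DOY {self.doy_start}..{self.doy_end}, got {len(rates)}"
            )
        if not np.all(np.isfinite(rates)):
            bad = int(np.flatnonzero(~np.isfinite(rates))[0])
            raise GrowthSeriesError(
                f"year {self.year}, DOY {self.doy_start + bad}: non-finite rate"
            )
        if np.any((rates < 0.0) | (rates > 1.0)):
            bad = int(np.flatnonzero((rates < 0.0) | (rates > 1.0))[0])
            raise GrowthSeriesError(
                f"year {self.year}, DOY {self.doy_start + bad}: rate "
                f"{rates[bad]} outside [0, 1]"
            )

    @property
    def n_days(self) -> int:
        return self.doy_end - self.doy_start + 1

    @property
    def doys(self) -> np.ndarray:
        return np.arange(self.doy_start, self.doy_end + 1)

    def rate_on_day(self, t: int) -> float:
        """Rate on within-season day ``t`` (0 = season start)."""
        return float(self.rates[t])


@dataclass(frozen=True)
class SummaryStats:
    """Distribution summary of one season's daily growth rates.

    These six statistics (plus the previous season's ``skew``) are the
    regressors of the seasonal inhibitor-supply regression.
    """

    sd: float
    median: float
    mad: float
    min: float
    max: float
    skew: float


def load_growth_series(path) -> dict[int, DailyGrowthSeries]:
    """Load per-year daily growth-rate series from a CSV file.

    The CSV must have columns ``year,doy,rate`` (optionally
    ``doy_start,doy_end``); days must be contiguous within each year.
    Returns a dict keyed by year.
    """
    df = pd.read_csv(path)
    required = {"year", "doy", "rate"}
    missing = required - set(df.columns)
    if missing:
        raise GrowthSeriesError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    out: dict[int, DailyGrowthSeries] = {}
    for year, grp in df.groupby("year", sort=True):
        grp = grp.sort_values("doy")
        doys = grp["doy"].to_numpy(dtype=int)
        gaps = np.flatnonzero(np.diff(doys) != 1)
        if gaps.size:
            raise GrowthSeriesError(
                f"year {year}: non-contiguous doy sequence "
                f"({doys[gaps[0]]} -> {doys[gaps[0] + 1]})"
            )
        rates = grp["rate"].to_numpy(dtype=float)
        bad = np.flatnonzero((rates < 0.0) | (rates > 1.0) | ~np.isfinite(rates))
        if bad.size:
            raise GrowthSeriesError(
                f"year {year}, doy {doys[bad[0]]}: rate {rates[bad[0]]} "
                f"outside [0, 1]"
            )
        if "doy_start" in grp.columns and grp["doy_start"].notna().any():
            start = int(grp["doy_start"].iloc[0])
            end = int(grp["doy_end"].iloc[0])
            if start != doys[0] or end != doys[-1]:
                raise GrowthSeriesError(
                    f"year {year}: declared season bounds {start}..{end} do "
                    f"not match data {doys[0]}..{doys[-1]}"
                )
        out[int(year)] = DailyGrowthSeries(
            year=int(year), doy_start=int(doys[0]), doy_end=int(doys[-1]),
            rates=rates,
        )
    return out


def season_stats(
    series: DailyGrowthSeries,
    *,
    sd_ddof: int = 1,
    mad_scale: float = 1.0,
) -> SummaryStats:
    """Summary statistics of a season's daily rate distribution.

    Conventions (configurable because the supply-regression coefficients were
    fitted under some fixed but unrecorded convention): ``sd`` is the sample
    standard deviation (n−1 denominator); ``mad`` is the raw median of
    absolute deviations from the median, unscaled by default (``mad_scale``
    can apply e.g. the 1.4826 normal-consistency factor); ``skew`` is the
    population moment coefficient g1 = m3 / m2^1.5, defined as 0 for a
    constant sequence.
    """
    x = series.rates
    if x.size == 0:
        raise GrowthSeriesError("cannot summarise an empty season")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med))) * mad_scale
    if np.ptp(x) == 0.0:
        skew = 0.0
    else:
        skew = float(sps.skew(x, bias=True))
    return SummaryStats(
        sd=float(np.std(x, ddof=sd_ddof)),
        median=med,
        mad=mad,
        min=float(np.min(x)),
        max=float(np.max(x)),
        skew=skew,
    )


def detect_stress_window(
    series: DailyGrowthSeries, t: int, *, min_run: int = 3
) -> bool:
    """True iff a climatic stress window immediately precedes day ``t``.

    A stress window exists when the daily rate strictly decreased on each of
    at least ``min_run`` consecutive day-to-day steps ending at within-season
    day ``t`` (0-based).  Days earlier than ``min_run`` return False —
    insufficient history, not an error.
    """
    if t < min_run:
        return False
    if t >= series.n_days:
        raise GrowthSeriesError(
            f"day {t} outside season of length {series.n_days}"
        )
    window = series.rates[t - min_run : t + 1]
    return bool(np.all(np.diff(window) < 0.0))


def build_average_season(
    collection: Mapping[int, DailyGrowthSeries] | Iterable[DailyGrowthSeries],
) -> DailyGrowthSeries:
    """Average several seasons into one synthetic "average growth season".

    Bounds are the rounded means of the per-year bounds; the rate on each DOY
    is the mean over all years whose season covers that DOY (alignment is by
    calendar DOY, not by day-within-season).  The result carries year 0.
    """
    if isinstance(collection, Mapping):
        seasons = list(collection.values())
    else:
        seasons = list(collection)
    if not seasons:
        raise GrowthSeriesError("cannot average an empty collection of seasons")
    start = int(np.floor(np.mean([s.doy_start for s in seasons]) + 0.5))
    end = int(np.floor(np.mean([s.doy_end for s in seasons]) + 0.5))
    rates = np.empty(end - start + 1, dtype=float)
    for i, doy in enumerate(range(start, end + 1)):
        vals = [
            s.rates[doy - s.doy_start]
            for s in seasons
            if s.doy_start <= doy <= s.doy_end
        ]
        if not vals:
            raise GrowthSeriesError(
                f"DOY {doy} of the average season is covered by no input year"
            )
        rates[i] = np.mean(vals)
    return DailyGrowthSeries(
        year=0, doy_start=start, doy_end=end, rates=np.clip(rates, 0.0, 1.0)
    )
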