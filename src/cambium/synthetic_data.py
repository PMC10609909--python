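"""Synthetic growth-rate seasons and full study fixtures with known truth.

No deposited forcing or anatomical data exist for the study system, so every
other module is exercised against generated data.  A season is a sine-arch
of daily integral growth rates over roughly DOY 127-285 — rising from small
but nonzero values at the threshold-bounded season edges to a mid-summer
maximum — with AR(1) weather noise, inter-annual variation in peak, edge
level and season bounds, and occasional multi-day strictly-declining
"stress dips" that the stress-window detector is meant to catch.  A study
fixture chains seasons into a multi-year record: true supplies from a known
regression, productions from the simulator under known parameters, plus the
truth needed for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np

from .cell_cycle import ParameterSet
from .env_series import DailyGrowthSeries, season_stats
from .supply_regression import SupplyRegression, predict_supply


@dataclass(frozen=True)
class FixtureConfig:
    """Everything that shapes a synthetic study; ``seed`` fixes it all.

    Defaults emulate the study conditions: ~40 usable seasons, average
    bounds DOY 127/285 with a few days of inter-annual jitter, a sine-arch
    rate curve whose peak and edge baseline vary year to year, a mid-summer
    drought depression whose severity varies from none to strong (the
    bimodal curve typical of semi-arid sites), mild positively-correlated
    daily noise, and up to a few >=3-day declining stress windows per
    season.  ``supply_noise_frac`` scales the optional
    Gaussian noise on the true supplies by the record's mean supply.
    """

    n_years: int = 40
    start_year: int = 1963
    doy_start: int = 127
    doy_end: int = 285
    bounds_jitter_sd: float = 4.0
    peak: float = 0.95
    peak_sd: float = 0.10
    peak_range: tuple[float, float] = (0.60, 1.00)
    baseline_range: tuple[float, float] = (0.005, 0.04)
    bell_exponent: float = 1.0
    ar_sigma: float = 0.04
    ar_rho: float = 0.6
    drought_depth_range: tuple[float, float] = (0.0, 0.55)
    drought_center_range: tuple[float, float] = (0.45, 0.65)
    drought_width_range: tuple[float, float] = (0.10, 0.20)
    dips_range: tuple[int, int] = (0, 3)
    dip_length_range: tuple[int, int] = (3, 6)
    dip_depth_range: tuple[float, float] = (0.4, 0.8)
    regression: SupplyRegression = field(default_factory=SupplyRegression)
    params: ParameterSet = field(default_factory=ParameterSet)
    production_noise: str = "none"      # none | rounding | poisson
    supply_noise_frac: float = 0.0
    skew_prev_default: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.doy_start >= self.doy_end:
            raise ValueError("doy_start must be < doy_end")
        if self.dip_length_range[0] < 3:
            raise ValueError("stress dips must be at least 3 days long")
        if self.production_noise not in ("none", "rounding", "poisson"):
            raise ValueError(
                f"unknown production_noise {self.production_noise!r}"
            )
        if not 0.0 <= self.ar_rho < 1.0:
            raise ValueError("ar_rho must lie in [0, 1)")
        if self.supply_noise_frac < 0.0:
            raise ValueError("supply_noise_frac must be >= 0")


def _gen_one_year(
    rng: np.random.Generator, config: FixtureConfig, year: int
) -> tuple[DailyGrowthSeries, list[tuple[int, int]]]:
    start = int(np.floor(rng.normal(config.doy_start, config.bounds_jitter_sd) + 0.5))
    end = int(np.floor(rng.normal(config.doy_end, config.bounds_jitter_sd) + 0.5))
    if end - start < 30:
        end = start + 30
    n = end - start + 1
    t = np.linspace(0.0, 1.0, n)
    peak = float(np.clip(rng.normal(config.peak, config.peak_sd), *config.peak_range))
    baseline = float(rng.uniform(*config.baseline_range))
    bell = baseline + peak * np.sin(np.pi * t) ** config.bell_exponent

    # Mid-summer drought depression of varying severity: semi-arid seasons
    # range from a clean arch to a strongly bimodal curve.
    depth = float(rng.uniform(*config.drought_depth_range))
    center = float(rng.uniform(*config.drought_center_range))
    width = float(rng.uniform(*config.drought_width_range))
    bell *= 1.0 - depth * np.exp(-0.5 * ((t - center) / width) ** 2)

    sigma, rho = config.ar_sigma, config.ar_rho
    noise = np.empty(n)
    noise[0] = rng.normal(0.0, sigma)
    innov = rng.normal(0.0, sigma * np.sqrt(1.0 - rho**2), size=n - 1)
    for i in range(1, n):
        noise[i] = rho * noise[i - 1] + innov[i - 1]
    rates = np.clip(bell + noise, 0.0, 1.0)

    dips: list[tuple[int, int]] = []
    n_dips = int(rng.integers(config.dips_range[0], config.dips_range[1] + 1))
    for _ in range(n_dips):
        m = int(rng.integers(
            config.dip_length_range[0], config.dip_length_range[1] + 1
        ))
        depth = float(rng.uniform(*config.dip_depth_range))
        placed = False
        for _attempt in range(20):
            s = int(rng.integers(n // 6, max(n - m - n // 6, n // 6 + 1)))
            if any(s - 1 <= e and d <= s + m for d, e in dips):
                continue
            v_prev = rates[s - 1]
            if v_prev <= 0.05:
                continue
            f = depth ** (1.0 / m)
            rates[s : s + m] = v_prev * f ** np.arange(1, m + 1)
            dips.append((s, s + m - 1))
            placed = True
            break
        if not placed:
            continue
    series = DailyGrowthSeries(
        year=year, doy_start=start, doy_end=end, rates=rates
    )
    return series, dips


def gen_growth_series_detailed(
    config: FixtureConfig,
) -> tuple[dict[int, DailyGrowthSeries], dict[int, list[tuple[int, int]]]]:
    """Generate per-year series plus the injected dip windows.

    Dip windows are (first, last) within-season day indices of each
    strictly-declining stress window.
    """
    rng = np.random.default_rng(config.seed)
    series: dict[int, DailyGrowthSeries] = {}
    dips: dict[int, list[tuple[int, int]]] = {}
    for year in range(config.start_year, config.start_year + config.n_years):
        series[year], dips[year] = _gen_one_year(rng, config, year)
    return series, dips


def gen_growth_series(config: FixtureConfig) -> dict[int, DailyGrowthSeries]:
    """Generate the per-year daily growth-rate series of a fixture."""
    return gen_growth_series_detailed(config)[0]


@dataclass
class StudyFixture:
    """A synthetic multi-year study with complete ground truth."""

    config: FixtureConfig
    series_by_year: dict[int, DailyGrowthSeries]
    dip_windows: dict[int, list[tuple[int, int]]]
    true_supplies: dict[int, float]         # noise-free regression values
    noisy_supplies: dict[int, float]        # supplies actually simulated
    true_production: dict[int, int]         # simulator output, pre obs-noise
    observed_production: dict[int, float]   # with the production noise model
    supply_noise_sd: float

    @property
    def truth(self) -> dict:
        """JSON-serialisable record of everything recovery tests need."""
        cfg = asdict(self.config)
        cfg["regression"] = asdict(self.config.regression)
        cfg["params"] = {
            k: v for k, v in asdict(self.config.params).items()
        }
        return {
            "config": cfg,
            "supply_noise_sd": self.supply_noise_sd,
            "years": sorted(self.series_by_year),
            "true_supplies": self.true_supplies,
            "noisy_supplies": self.noisy_supplies,
            "true_production": self.true_production,
            "observed_production": self.observed_production,
            "dip_windows": {str(y): w for y, w in self.dip_windows.items()},
        }


def gen_study_fixture(config: FixtureConfig) -> StudyFixture:
    """Generate a full study fixture under a known regression and parameters.

    Supplies come from the configured regression applied to each season's
    statistics (previous-season skewness chained through the record, the
    configured default for the first year), optionally perturbed by Gaussian
    noise of sd ``supply_noise_frac`` x mean supply.  Productions come from
    the season simulator under the configured parameters, optionally passed
    through the production noise model ("rounding": +/-1-cell measurement
    error; "poisson": Poisson resampling of the count).
    """
    series_by_year, dip_windows = gen_growth_series_detailed(config)
    years = sorted(series_by_year)
    rng = np.random.default_rng(config.seed + 1_000_003)

    stats = {y: season_stats(series_by_year[y]) for y in years}
    true_supplies: dict[int, float] = {}
    for year in years:
        skew_prev = (
            stats[year - 1].skew
            if (year - 1) in stats
            else config.skew_prev_default
        )
        true_supplies[year] = predict_supply(
            stats[year], skew_prev, config.regression
        ).value

    sigma = config.supply_noise_frac * float(
        np.mean(list(true_supplies.values()))
    )
    noisy_supplies = {
        y: true_supplies[y] + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
        for y in years
    }

    from .season_sim import simulate_season  # deferred: avoid import cycle

    true_production: dict[int, int] = {}
    observed: dict[int, float] = {}
    for year in years:
        prod = simulate_season(
            series_by_year[year], config.params, noisy_supplies[year]
        ).production
        true_production[year] = prod
        if config.production_noise == "none":
            obs = float(prod)
        elif config.production_noise == "rounding":
            obs = float(max(prod + int(rng.integers(-1, 2)), 0))
        else:
            obs = float(rng.poisson(prod))
        observed[year] = obs
    return StudyFixture(
        config=config,
        series_by_year=series_by_year,
        dip_windows=dip_windows,
        true_supplies=true_supplies,
        noisy_supplies=noisy_supplies,
        true_production=true_production,
        observed_production=observed,
        supply_noise_sd=sigma,
    )


def write_fixture(fixture: StudyFixture, outdir) -> dict[str, str]:
    """Write a fixture in the CSV/JSON dialects the loaders read back."""
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for year in sorted(fixture.series_by_year):
        s = fixture.series_by_year[year]
        for doy, rate in zip(s.doys, s.rates):
            rows.append({"year": year, "doy": int(doy), "rate": rate})
    series_path = outdir / "series.csv"
    pd.DataFrame(rows).to_csv(series_path, index=False, float_format="%.8g")

    production_path = outdir / "production.csv"
    pd.DataFrame(
        {
            "year": sorted(fixture.observed_production),
            "cells": [
                fixture.observed_production[y]
                for y in sorted(fixture.observed_production)
            ],
        }
    ).to_csv(production_path, index=False)

    truth_path = outdir / "truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(fixture.truth, fh, indent=2, default=float)

    regression_path = outdir / "regression.json"
    fixture.config.regression.to_json(regression_path)
    return {
        "series": str(series_path),
        "production": str(production_path),
        "truth": str(truth_path),
        "regression": str(regression_path),
    }
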