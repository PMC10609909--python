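"""One growing season of cambial activity.

The season starts with a single dormant initial cell holding the whole
inhibitor supply.  It is carried to its first division at a fixed linear
rate; from then on every cell in the radial file advances concurrently in
daily steps — within a day each cell's phase crossings are solved
analytically, and its G1 Gompertz rate is re-evaluated at day and phase
boundaries.  Divisions split the inhibitor asymmetrically; cells whose
concentration has dropped below the minimum are exported to the enlargement
zone (cell production).  The season ends when the environmental season ends
or when no cell in the row retains a divisible concentration — amounts are
conserved, so the supply is "consumed" only in the sense that no cell can
divide any more.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.stats import pearsonr

from .cell_cycle import (
    CambialCell,
    ParameterSet,
    advance_cell,
    concentration,
    divide_cell,
    g1_rate,
    initial_linear_rate,
    should_exit,
)
from .env_series import DailyGrowthSeries, detect_stress_window

#: Reported time resolution, days.
TIME_RESOLUTION = 0.001


def _round_t(t: float) -> float:
    return round(t, 3)


@dataclass(frozen=True)
class DivisionRecord:
    """Per-division output row.

    All times are in days from season start, reported at 0.001 d resolution.
    ``appearance_date`` is when the dividing cell itself was born;
    ``division_time`` is when it split.  ``concentration_at_M`` is the
    inhibitor concentration at the division diameter — the quantity checked
    against the minimum threshold to decide whether the cell divides or is
    exported.
    """

    appearance_date: float
    g1_time: float
    s_time: float
    g2_time: float
    m_time: float
    cycle_time: float
    inhibitor_received: float
    g1_rate_at_birth: float
    concentration_at_M: float
    cell_id: str
    mother_id: str
    division_time: float
    stressed: bool


class ExportRecord(NamedTuple):
    """A cell transferred to the enlargement zone."""

    time: float
    cell_id: str
    inhibitor: float
    at_birth: bool           # exported immediately at birth (below threshold)


@dataclass
class SeasonResult:
    """Outcome of one simulated growing season."""

    year: int
    supply_used: float
    production: int
    simulated_season_length: float
    env_season_length: int
    termination_reason: str           # "supply_consumed" | "env_season_end"
    division_log: list[DivisionRecord] = field(default_factory=list)
    export_log: list[ExportRecord] = field(default_factory=list)
    kinetics: pd.DataFrame = field(default_factory=pd.DataFrame)
    final_row: list[CambialCell] = field(default_factory=list)
    first_division_time: float = float("nan")

    @property
    def n_divisions(self) -> int:
        return len(self.division_log)

    @property
    def exported_inhibitor(self) -> float:
        return sum(e.inhibitor for e in self.export_log)


def _index(row: list[CambialCell], cell: CambialCell) -> int:
    for i, c in enumerate(row):
        if c is cell:
            return i
    raise ValueError(f"cell {cell.cell_id} not in row")


def _remove(row: list[CambialCell], cell: CambialCell) -> None:
    del row[_index(row, cell)]


def _regime_rate(
    cell: CambialCell, gr_today: float, params: ParameterSet, lin_rate: float
) -> float:
    if cell.first_cycle_linear:
        return lin_rate
    if cell.phase == "G1":
        C = concentration(cell.inhibitor, cell.diameter)
        return g1_rate(C, cell.stressed, gr_today, params)
    return params.V0


def simulate_season(
    series: DailyGrowthSeries,
    params: ParameterSet,
    supply: float,
    *,
    max_divisions: int = 1_000_000,
) -> SeasonResult:
    """Simulate one growing season and return its full result bundle.

    ``supply`` is the inhibitor amount placed in the initial cell at t = 0.
    A supply at or below C_min * D_init (including the nonphysical negative
    predictions of the supply regression) yields production 0 without
    stepping.  Identical inputs produce identical results — the simulator
    has no internal randomness.
    """
    if not math.isfinite(supply):
        raise ValueError(f"supply must be finite, got {supply}")
    if not isinstance(params, ParameterSet):
        raise TypeError("params must be a ParameterSet")

    n_days = series.n_days
    initial = CambialCell(
        cell_id="0",
        mother_id="",
        position=0,
        diameter=params.D_init,
        phase="G1",
        inhibitor=max(supply, 0.0),
        born_at=0.0,
        phase_entry_times={"G1": 0.0},
        is_initial=True,
        first_cycle_linear=True,
    )
    lin_rate = initial_linear_rate(params)
    initial.g1_rate_at_birth = lin_rate

    result = SeasonResult(
        year=series.year,
        supply_used=supply,
        production=0,
        simulated_season_length=0.0,
        env_season_length=n_days,
        termination_reason="supply_consumed",
    )

    if supply <= params.C_min * params.D_init:
        result.final_row = [initial]
        result.kinetics = _empty_kinetics()
        return result

    row: list[CambialCell] = [initial]
    exported_inhibitor = 0.0
    last_event_time = 0.0
    kin_rows: list[dict] = []
    reason = "env_season_end"

    for day in range(n_days):
        gr_today = series.rate_on_day(day)
        day_end = float(day + 1)

        g1_rates = [
            _regime_rate(c, gr_today, params, lin_rate)
            for c in row
            if c.phase == "G1"
        ]
        kin_rows.append(
            {
                "day": day,
                "g1_rate_mean": float(np.mean(g1_rates)) if g1_rates else np.nan,
                "concentration_mean": float(
                    np.mean([concentration(c.inhibitor, c.diameter) for c in row])
                )
                if row
                else np.nan,
                "gr": gr_today,
                "n_cells": len(row),
                "inhibitor_in_row": float(sum(c.inhibitor for c in row)),
                "inhibitor_exported": exported_inhibitor,
            }
        )

        queue: deque[tuple[CambialCell, float]] = deque(
            (cell, float(day)) for cell in row
        )
        while queue:
            cell, t_now = queue.popleft()
            if cell.phase == "M" and cell.diameter >= params.D_div:
                continue  # initial cell stuck below threshold at D_div
            rate = _regime_rate(cell, gr_today, params, lin_rate)
            if rate <= 0.0 or t_now >= day_end:
                continue
            events = advance_cell(cell, rate, day_end - t_now, params, t0=t_now)
            if events:
                last_event_time = max(last_event_time, events[-1].time)
            if not events or events[-1].kind != "ready_to_divide":
                continue  # advanced to the day boundary without reaching D_div
            t_div = events[-1].time
            conc_at_M = concentration(cell.inhibitor, cell.diameter)
            if conc_at_M < params.C_min:
                if cell.is_initial:
                    # The initial cell never exports; it sits at the division
                    # diameter and the row can only drain.
                    continue
                _remove(row, cell)
                result.export_log.append(
                    ExportRecord(
                        _round_t(t_div), cell.cell_id, cell.inhibitor, False
                    )
                )
                result.production += 1
                continue
            # division
            if len(result.division_log) >= max_divisions:
                raise RuntimeError(f"division cap ({max_divisions}) exceeded")
            stress = detect_stress_window(series, day)
            prox, dist = divide_cell(
                cell, params.alpha, stress, t=t_div, params=params
            )
            if math.isnan(result.first_division_time):
                result.first_division_time = _round_t(t_div)
            result.division_log.append(
                _make_division_record(cell, t_div, conc_at_M, stress)
            )
            idx = _index(row, cell)
            row[idx : idx + 1] = [prox, dist]
            for daughter in (prox, dist):
                C_birth = concentration(daughter.inhibitor, daughter.diameter)
                daughter.g1_rate_at_birth = g1_rate(
                    C_birth, daughter.stressed, gr_today, params
                )
                if not daughter.is_initial and should_exit(daughter, params):
                    _remove(row, daughter)
                    result.export_log.append(
                        ExportRecord(
                            _round_t(t_div), daughter.cell_id,
                            daughter.inhibitor, True,
                        )
                    )
                    result.production += 1
                else:
                    queue.append((daughter, t_div))

        for pos, cell in enumerate(row):
            cell.position = pos
        exported_inhibitor = sum(e.inhibitor for e in result.export_log)

        if not any(
            concentration(c.inhibitor, c.diameter) >= params.C_min for c in row
        ):
            reason = "supply_consumed"
            break

    result.termination_reason = reason
    result.simulated_season_length = (
        float(n_days) if reason == "env_season_end" else _round_t(last_event_time)
    )
    result.final_row = row
    result.division_log.sort(key=lambda r: (r.division_time, r.cell_id))
    result.export_log.sort(key=lambda e: (e.time, e.cell_id))
    result.kinetics = pd.DataFrame(
        kin_rows,
        columns=[
            "day", "g1_rate_mean", "concentration_mean", "gr", "n_cells",
            "inhibitor_in_row", "inhibitor_exported",
        ],
    )
    return result


def _empty_kinetics() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "day", "g1_rate_mean", "concentration_mean", "gr", "n_cells",
            "inhibitor_in_row", "inhibitor_exported",
        ]
    )


def _make_division_record(
    cell: CambialCell, t_div: float, conc_at_M: float, stressed: bool
) -> DivisionRecord:
    entries = cell.phase_entry_times
    t_s = entries.get("S", cell.born_at)
    t_g2 = entries.get("G2", t_s)
    t_m = entries.get("M", t_g2)
    return DivisionRecord(
        appearance_date=_round_t(cell.born_at),
        g1_time=_round_t(t_s - cell.born_at),
        s_time=_round_t(t_g2 - t_s),
        g2_time=_round_t(t_m - t_g2),
        m_time=_round_t(t_div - t_m),
        cycle_time=_round_t(t_div - cell.born_at),
        inhibitor_received=cell.inhibitor,
        g1_rate_at_birth=cell.g1_rate_at_birth,
        concentration_at_M=conc_at_M,
        cell_id=cell.cell_id,
        mother_id=cell.mother_id,
        division_time=_round_t(t_div),
        stressed=stressed,
    )


def extract_kinetics(result: SeasonResult) -> pd.DataFrame:
    """Daily kinetics of a season: mean G1 rate of cells in G1, mean
    inhibitor concentration over the row, and the external growth rate.

    Days with no cell in G1 carry NaN (a missing-value marker, not zero).
    """
    if result.kinetics.empty:
        raise ValueError("season result carries no simulated days")
    return result.kinetics[
        ["day", "g1_rate_mean", "concentration_mean", "gr"]
    ].copy()


class PairCorrelation(NamedTuple):
    r: float
    r_squared: float


def kinetics_correlations(
    kinetics: pd.DataFrame, smoothing_parameter: float | None = None
) -> dict[tuple[str, str], PairCorrelation]:
    """Pairwise Pearson correlations among the smoothed kinetics series.

    Each of (G1 rate, mean concentration, external Gr) is smoothed with a
    cubic smoothing spline (``smoothing_parameter`` is the spline's
    regularisation weight lambda; None lets generalised cross-validation
    choose it) before correlating.  Requires at least 10 days on which all
    three series are defined.
    """
    cols = ["g1_rate_mean", "concentration_mean", "gr"]
    valid = kinetics.dropna(subset=cols)
    if len(valid) < 10:
        raise ValueError(
            f"need at least 10 valid days for correlations, got {len(valid)}"
        )
    x = valid["day"].to_numpy(dtype=float)
    smoothed = {}
    for col in cols:
        y = valid[col].to_numpy(dtype=float)
        if np.ptp(y) == 0.0:
            smoothed[col] = y
        else:
            spline = make_smoothing_spline(x, y, lam=smoothing_parameter)
            smoothed[col] = spline(x)
    out: dict[tuple[str, str], PairCorrelation] = {}
    for a, b in (
        ("g1_rate_mean", "gr"),
        ("concentration_mean", "gr"),
        ("g1_rate_mean", "concentration_mean"),
    ):
        r = float(pearsonr(smoothed[a], smoothed[b])[0])
        out[(a, b)] = PairCorrelation(r=r, r_squared=r * r)
    return out


# ---------------------------------------------------------------------------
# On-disk artifacts

DIVISION_LOG_COLUMNS = [
    "appearance_date", "g1_time", "s_time", "g2_time", "m_time", "cycle_time",
    "inhibitor_received", "g1_rate_at_birth", "concentration_at_M",
    "cell_id", "mother_id", "division_time", "stressed",
]


def division_log_frame(result: SeasonResult) -> pd.DataFrame:
    rows = [
        {col: getattr(rec, col) for col in DIVISION_LOG_COLUMNS}
        for rec in result.division_log
    ]
    return pd.DataFrame(rows, columns=DIVISION_LOG_COLUMNS)


def write_division_log(result: SeasonResult, path) -> None:
    division_log_frame(result).to_csv(path, index=False, float_format="%.6g")


def season_summary(result: SeasonResult) -> dict:
    return {
        "year": result.year,
        "supply": result.supply_used,
        "production": result.production,
        "n_divisions": result.n_divisions,
        "simulated_season_length": result.simulated_season_length,
        "env_season_length": result.env_season_length,
        "termination_reason": result.termination_reason,
        "first_division_time": (
            None
            if math.isnan(result.first_division_time)
            else result.first_division_time
        ),
    }


def write_kinetics(result: SeasonResult, path) -> None:
    extract_kinetics(result).to_csv(path, index=False, float_format="%.6g")
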