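"""Naive fixed-step reference simulator.

Integrates the same model semantics as the event-driven engine — G1
Gompertz rate held piecewise-constant and refreshed at day and phase
boundaries, S/G2/M at V0, asymmetric division, birth/division-diameter
exit checks, day-end termination — but by explicit dt stepping with
threshold checks instead of analytic event solving.  Kept deliberately
independent of the package's season engine; shares only the elementary
rate/threshold definitions re-derived inline.
"""

from __future__ import annotations

import math

from cambium.cell_cycle import ParameterSet
from cambium.env_series import DailyGrowthSeries


class _Cell:
    __slots__ = (
        "cid", "mother", "diameter", "phase", "inh", "born", "stressed",
        "linear", "initial", "stuck", "rate",
    )

    def __init__(self, cid, mother, diameter, phase, inh, born, stressed,
                 linear, initial):
        self.cid = cid
        self.mother = mother
        self.diameter = diameter
        self.phase = phase
        self.inh = inh
        self.born = born
        self.stressed = stressed
        self.linear = linear
        self.initial = initial
        self.stuck = False
        self.rate = 0.0


def _g1_rate(c: _Cell, p: ParameterSet) -> float:
    conc = c.inh / c.diameter
    arg = p.c * conc
    if c.stressed:
        arg = arg * p.S_stress if p.stress_mode == "literal" else arg / p.S_stress
    return math.exp(-math.exp(-arg))


def _regime(c: _Cell, p: ParameterSet, lin_rate: float, gr: float) -> float:
    if c.linear:
        return lin_rate
    if c.phase == "G1":
        r = _g1_rate(c, p)
        if p.g1_env_coupling == "multiplicative":
            r *= gr
        return r
    return p.V0


def _stressed_day(rates, day: int) -> bool:
    if day < 3:
        return False
    return rates[day - 3] > rates[day - 2] > rates[day - 1] > rates[day]


def simulate_fixed_step(
    series: DailyGrowthSeries,
    params: ParameterSet,
    supply: float,
    dt: float = 0.0005,
) -> dict:
    """Brute-force dt-step simulation of one season.

    Returns production, division times keyed by the dividing cell's id
    (birth time, division time), and export times keyed by cell id.
    """
    p = params
    if supply <= p.C_min * p.D_init:
        return {"production": 0, "divisions": {}, "exports": {}}
    lin_rate = (p.D_div - p.D_init) / p.d_init
    rates = [float(r) for r in series.rates]
    steps = round(1.0 / dt)
    cells = [
        _Cell("0", "", p.D_init, "G1", supply, 0.0, False, True, True)
    ]
    production = 0
    divisions: dict[str, tuple[float, float]] = {}
    exports: dict[str, float] = {}
    next_threshold = {"G1": p.D_S, "S": p.D_G2, "G2": p.D_M, "M": p.D_div}
    next_phase = {"G1": "S", "S": "G2", "G2": "M"}

    for day in range(series.n_days):
        gr = rates[day]
        for c in cells:
            c.rate = _regime(c, p, lin_rate, gr)
        for k in range(steps):
            t = day + (k + 1) * dt
            born_this_step: list[_Cell] = []
            removed: list[_Cell] = []
            for c in cells:
                if c.stuck:
                    continue
                c.diameter += c.rate * dt
                thr = next_threshold[c.phase]
                if c.diameter < thr:
                    continue
                if c.phase != "M":
                    c.phase = next_phase[c.phase]
                    c.rate = _regime(c, p, lin_rate, gr)
                    continue
                # ready to divide at the division diameter
                c.diameter = p.D_div
                conc = c.inh / p.D_div
                if conc < p.C_min:
                    if c.initial:
                        c.stuck = True
                    else:
                        removed.append(c)
                        exports[c.cid] = t
                        production += 1
                    continue
                stress = _stressed_day(rates, day)
                divisions[c.cid] = (c.born, t)
                half = c.diameter / 2.0
                prox = _Cell(
                    c.cid + ".p", c.cid, half, "G1", c.inh * p.alpha, t,
                    stress, False, c.initial,
                )
                dist = _Cell(
                    c.cid + ".d", c.cid, half,
                    "G1", c.inh - c.inh * p.alpha, t, stress, False, False,
                )
                removed.append(c)
                for d in (prox, dist):
                    d.rate = _regime(d, p, lin_rate, gr)
                    if not d.initial and d.inh / d.diameter < p.C_min:
                        exports[d.cid] = t
                        production += 1
                    else:
                        born_this_step.append(d)
            if removed:
                cells = [c for c in cells if c not in removed]
            cells.extend(born_this_step)
        if not any(c.inh / c.diameter >= p.C_min for c in cells):
            break
    return {"production": production, "divisions": divisions, "exports": exports}
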