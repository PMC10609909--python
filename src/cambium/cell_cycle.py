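"""Per-cell mechanics of the cambial cell cycle.

A cambial cell progresses through G1 → S → G2 → M by growing in radial
diameter; each phase transition fires when the diameter reaches a critical
size.  Growth in S/G2/M runs at the constant rate V0; growth in G1 follows a
Gompertz function of the cell's inhibitor concentration, so inhibitor-rich
cells near the initial cell cycle faster.  At the critical division diameter
a cell either divides — the inhibitor amount is split asymmetrically between
the two half-size daughters, the share alpha going to the daughter closer to
the initial cell — or, when its inhibitor concentration has fallen below the
minimum threshold, loses the ability to divide and is exported to the
enlargement zone.  That export count over a season is the model's cell
production, the tree-ring cell-count proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple

PHASES = ("G1", "S", "G2", "M")


@dataclass(frozen=True)
class ParameterSet:
    """Season-invariant model parameters.

    Diameters are in micrometres, rates in micrometres per day, inhibitor
    amounts and concentrations in relative units.

    Attributes
    ----------
    D_S, D_G2, D_M : float
        Critical diameters for the G1→S, S→G2 and G2→M transitions.
    D_div : float
        Critical diameter at which a cell in M is ready to divide.
    C_min : float
        Minimum inhibitor concentration required for division; below it a
        cell is exported to the enlargement zone.
    V0 : float
        Constant growth rate in phases S, G2 and M.
    c : float
        Gompertz rate parameter for phase G1.
    D_init : float
        Diameter of the dormant initial cell at season start.
    S_stress : float
        Stress coefficient applied inside the G1 Gompertz exponent for cells
        born from a stress-flagged division.
    alpha : float
        Inhibitor share handed to the proximal daughter at division,
        in (0, 1).
    d_init : float
        Duration (days) of the initial cell's first, linear-rate cycle.
    stress_mode : {"literal", "reciprocal"}
        "literal" multiplies the Gompertz exponent argument by S_stress as
        the model equation is written (which *raises* the rate);
        "reciprocal" divides by S_stress instead, matching the stated
        biology of stress slowing growth.
    g1_env_coupling : {"none", "multiplicative"}
        Optionally scale the G1 rate by the day's external growth rate.
    """

    D_S: float = 8.5
    D_G2: float = 8.7
    D_M: float = 9.0
    D_div: float = 9.5
    C_min: float = 0.03
    V0: float = 0.68
    c: float = 0.071
    D_init: float = 2.0
    S_stress: float = 100.0
    alpha: float = 0.8286
    d_init: float = 7.5
    stress_mode: Literal["literal", "reciprocal"] = "literal"
    g1_env_coupling: Literal["none", "multiplicative"] = "none"

    def __post_init__(self) -> None:
        if not (0.0 < self.D_init < self.D_S < self.D_G2 < self.D_M < self.D_div):
            raise ValueError(
                "diameter thresholds must satisfy "
                "0 < D_init < D_S < D_G2 < D_M < D_div, got "
                f"{self.D_init}, {self.D_S}, {self.D_G2}, {self.D_M}, {self.D_div}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.C_min <= 0.0 and self.C_min != 0.0:
            raise ValueError(f"C_min must be >= 0, got {self.C_min}")
        for name in ("V0", "d_init", "S_stress"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.stress_mode not in ("literal", "reciprocal"):
            raise ValueError(f"unknown stress_mode {self.stress_mode!r}")
        if self.g1_env_coupling not in ("none", "multiplicative"):
            raise ValueError(f"unknown g1_env_coupling {self.g1_env_coupling!r}")

    def replace(self, **changes) -> "ParameterSet":
        return replace(self, **changes)

    def phase_of_diameter(self, diameter: float) -> str:
        if diameter < self.D_S:
            return "G1"
        if diameter < self.D_G2:
            return "S"
        if diameter < self.D_M:
            return "G2"
        return "M"


@dataclass
class CambialCell:
    """One cell of the radial file.

    ``position`` is the index in the row (the initial cell sits at 0);
    ``born_at`` is the within-season birth time in days.  ``stressed`` marks
    cells born from a stress-flagged division — their G1 regime uses the
    stress branch of the Gompertz rate.  ``first_cycle_linear`` marks the
    dormant initial cell before its first division, which grows at a fixed
    linear rate through all phases.
    """

    cell_id: str
    mother_id: str
    position: int
    diameter: float
    phase: str
    inhibitor: float
    born_at: float
    phase_entry_times: dict = field(default_factory=dict)
    stressed: bool = False
    is_initial: bool = False
    first_cycle_linear: bool = False
    g1_rate_at_birth: float = float("nan")

    def __post_init__(self) -> None:
        if self.diameter <= 0.0:
            raise ValueError("cell diameter must be positive")
        if self.inhibitor < 0.0:
            raise ValueError("cell inhibitor amount must be non-negative")
        if self.position < 0:
            raise ValueError("cell position must be non-negative")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")


class PhaseEvent(NamedTuple):
    """A within-day event: a phase entry or division readiness."""

    time: float              # days from season start
    kind: str                # "enter_S" | "enter_G2" | "enter_M" | "ready_to_divide"
    cell_id: str


def concentration(inhibitor: float, diameter: float) -> float:
    """Inhibitor concentration: amount divided by radial diameter."""
    if diameter <= 0.0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    return inhibitor / diameter


def g1_rate(
    C: float, stressed: bool, gr_today: float, params: ParameterSet
) -> float:
    """Gompertz growth rate (µm/day) of a cell in phase G1.

    Unstressed: exp(−exp(−c·C)).  Stressed cells use c·S_stress·C in
    literal mode or c·C/S_stress in reciprocal mode.  With multiplicative
    environmental coupling the result is scaled by the day's external
    growth rate.  The value lies in (0, 1] (coupling may push it to 0 only
    when the external rate is 0).
    """
    if C < 0.0:
        raise ValueError(f"concentration must be non-negative, got {C}")
    arg = params.c * C
    if stressed:
        if params.stress_mode == "literal":
            arg *= params.S_stress
        else:
            arg /= params.S_stress
    rate = math.exp(-math.exp(-arg))
    if params.g1_env_coupling == "multiplicative":
        rate *= gr_today
    return rate


def initial_linear_rate(params: ParameterSet) -> float:
    """Constant rate (µm/day) of the initial cell's first cycle.

    Carries the dormant initial cell from D_init to the division diameter
    over the configured d_init days.
    """
    if params.d_init <= 0.0:
        raise ValueError(f"d_init must be positive, got {params.d_init}")
    return (params.D_div - params.D_init) / params.d_init


_NEXT_PHASE = {"G1": "S", "S": "G2", "G2": "M"}


def _phase_threshold(phase: str, params: ParameterSet) -> float:
    return {
        "G1": params.D_S, "S": params.D_G2, "G2": params.D_M, "M": params.D_div
    }[phase]


def advance_cell(
    cell: CambialCell,
    rate: float,
    time_budget: float,
    params: ParameterSet,
    *,
    t0: float = 0.0,
) -> list[PhaseEvent]:
    """Advance one cell analytically for up to ``time_budget`` days.

    ``rate`` is the rate of the cell's *current* regime: the Gompertz G1
    rate for a G1 cell (held constant for the call — callers re-evaluate it
    at day and phase boundaries), or the fixed linear rate for the initial
    cell's first cycle, which persists through every phase.  After leaving
    G1 a normal cell grows at V0.  Diameter grows linearly within each
    regime and phase-boundary crossings are solved exactly.  A cell reaching
    the division diameter stops there and emits a ``ready_to_divide`` event.

    The cell is updated in place; the ordered events are returned.
    """
    if rate < 0.0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if time_budget <= 0.0:
        raise ValueError(f"time_budget must be positive, got {time_budget}")
    events: list[PhaseEvent] = []
    t = t0
    remaining = time_budget
    while remaining > 0.0:
        if cell.phase == "M" and cell.diameter >= params.D_div:
            break
        if cell.phase == "G1" or cell.first_cycle_linear:
            r = rate
        else:
            r = params.V0
        if r <= 0.0:
            break
        threshold = _phase_threshold(cell.phase, params)
        dt_cross = (threshold - cell.diameter) / r
        if dt_cross <= remaining:
            t += dt_cross
            remaining -= dt_cross
            cell.diameter = threshold
            if cell.phase == "M":
                events.append(PhaseEvent(t, "ready_to_divide", cell.cell_id))
                break
            nxt = _NEXT_PHASE[cell.phase]
            cell.phase = nxt
            cell.phase_entry_times[nxt] = t
            events.append(PhaseEvent(t, f"enter_{nxt}", cell.cell_id))
        else:
            cell.diameter += r * remaining
            t += remaining
            remaining = 0.0
    return events


def divide_cell(
    mother: CambialCell,
    alpha: float,
    stress_flag: bool,
    *,
    t: float | None = None,
    params: ParameterSet | None = None,
) -> tuple[CambialCell, CambialCell]:
    """Split a ready-to-divide mother into two half-size G1 daughters.

    The proximal daughter (same position as the mother, closer to the
    initial cell) receives the share ``alpha`` of the mother's inhibitor,
    the distal daughter (position + 1) the remainder; amounts are conserved
    exactly.  Both daughters inherit ``stress_flag`` for their G1 regime.
    Lineage IDs extend the mother's with ``.p`` / ``.d``.  If ``params`` is
    given, attempting to divide below the minimum concentration raises —
    such a cell must be exported instead.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if params is not None:
        if mother.phase != "M" or mother.diameter < params.D_div:
            raise ValueError(
                f"cell {mother.cell_id} is not ready to divide "
                f"(phase {mother.phase}, diameter {mother.diameter})"
            )
        if concentration(mother.inhibitor, mother.diameter) < params.C_min:
            raise ValueError(
                f"cell {mother.cell_id} is below the minimum division "
                "concentration and must be exported, not divided"
            )
    born = mother.born_at if t is None else t
    half = mother.diameter / 2.0
    prox_inh = mother.inhibitor * alpha
    dist_inh = mother.inhibitor - prox_inh   # exact conservation
    proximal = CambialCell(
        cell_id=mother.cell_id + ".p",
        mother_id=mother.cell_id,
        position=mother.position,
        diameter=half,
        phase="G1",
        inhibitor=prox_inh,
        born_at=born,
        phase_entry_times={"G1": born},
        stressed=stress_flag,
        is_initial=mother.is_initial,
    )
    distal = CambialCell(
        cell_id=mother.cell_id + ".d",
        mother_id=mother.cell_id,
        position=mother.position + 1,
        diameter=half,
        phase="G1",
        inhibitor=dist_inh,
        born_at=born,
        phase_entry_times={"G1": born},
        stressed=stress_flag,
        is_initial=False,
    )
    return proximal, distal


def should_exit(cell: CambialCell, params: ParameterSet) -> bool:
    """True iff the cell has lost the ability to divide.

    Exit is strict: concentration exactly equal to C_min retains division
    ability.  Evaluated at birth and again when the cell reaches the
    division diameter.
    """
    return concentration(cell.inhibitor, cell.diameter) < params.C_min
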