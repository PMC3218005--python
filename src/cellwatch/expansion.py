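"""Serial-passage cell-yield calculator.

Given a target cell number, an initial dish count and a fixed
subculture ratio (1:8 by default — every harvested dish seeds eight new
ones), decide after each hemocytometer count whether the experiment can
stop.  The latest harvest total (dishes x cells per dish) is compared
against the target; if it falls short, the dish count is multiplied by
the ratio and the run continues into the next passage.

Messages mirror the bench protocol verbatim: "Continue experiment" /
"Stop experiment".
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

CONTINUE = "continue"
STOP = "stop"

CONTINUE_MESSAGE = "Continue experiment"
STOP_MESSAGE = "Stop experiment"


@dataclass(frozen=True)
class HarvestRecord:
    passage: int
    dishes: int
    cells_per_dish: float
    total_harvested: float


@dataclass(frozen=True)
class ExpansionState:
    target_cells: float
    dishes_current: int
    passage_number: int = 1
    subculture_ratio: int = 8
    history: tuple = field(default_factory=tuple)
    decision: str = CONTINUE

    @property
    def message(self) -> str:
        return STOP_MESSAGE if self.decision == STOP else CONTINUE_MESSAGE


def start_run(target_cells: float, initial_dishes: int,
              subculture_ratio: int = 8) -> ExpansionState:
    """Open a run at passage 1 with an empty harvest history."""
    if target_cells <= 0:
        raise ValueError("target_cells must be positive")
    if initial_dishes < 1:
        raise ValueError("initial_dishes must be >= 1")
    if subculture_ratio < 1:
        raise ValueError("subculture_ratio must be >= 1")
    return ExpansionState(target_cells=float(target_cells),
                          dishes_current=int(initial_dishes),
                          subculture_ratio=int(subculture_ratio))


def record_harvest(state: ExpansionState, cells_per_dish: float) -> ExpansionState:
    """Log one passage's hemocytometer count and decide continue/stop.

    Stops when dishes x cells_per_dish meets the target; otherwise
    multiplies the dish count by the subculture ratio and advances the
    passage number.
    """
    if state.decision == STOP:
        raise ValueError("run already stopped; cannot record further harvests")
    if cells_per_dish < 0:
        raise ValueError("cells_per_dish must be >= 0")
    total = state.dishes_current * float(cells_per_dish)
    rec = HarvestRecord(state.passage_number, state.dishes_current,
                        float(cells_per_dish), total)
    history = state.history + (rec,)
    if total >= state.target_cells:
        return replace(state, history=history, decision=STOP)
    return replace(state, history=history,
                   dishes_current=state.dishes_current * state.subculture_ratio,
                   passage_number=state.passage_number + 1)


def passages_to_target(target: float, initial_dishes: int, yield_per_dish: float,
                       ratio: int = 8) -> int:
    """Smallest p >= 1 with initial_dishes * ratio^(p-1) * yield_per_dish >= target.

    Closed form via the ceiling of a logarithm, with an integer fix-up
    pass to absorb floating-point edge cases at exact-equality
    boundaries.
    """
    if target <= 0 or initial_dishes < 1 or yield_per_dish <= 0 or ratio < 1:
        raise ValueError("all arguments must be positive (dishes/ratio >= 1)")
    first = initial_dishes * yield_per_dish
    if first >= target or ratio == 1:
        if first < target:
            raise ValueError("yield never reaches target with ratio 1")
        return 1
    p = 1 + max(0, math.ceil(math.log(target / first) / math.log(ratio)))
    while initial_dishes * ratio ** (p - 1) * yield_per_dish < target:
        p += 1
    while p > 1 and initial_dishes * ratio ** (p - 2) * yield_per_dish >= target:
        p -= 1
    return p
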