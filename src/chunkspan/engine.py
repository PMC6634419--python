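"""Block administration: pacing, operation-span interleaving, stop rule.

A block presents its trials in ascending-length order.  Simple-span blocks
pace items at 1 s with a 500 ms inter-item interval; complex-span blocks use
the operation-span procedure — an equation to be judged true/false (3 s
deadline) precedes every to-be-remembered item.  Administration halts
permanently once all four scored trials of one list length have been failed;
practice trials never count toward the stop rule.

The engine is agnostic about who responds: any object with ``recall(trial)``
(returning an ordered token sequence) and, for complex span, ``judge(eq)``
(returning a bool) can be administered — synthetic participants, scripted
test responders, or replayed humans alike.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Protocol, Sequence, Tuple

import numpy as np

from .stimuli import TrialSpec, TRIALS_PER_LENGTH

__all__ = [
    "TASK_TYPES",
    "CONDITIONS",
    "CELLS",
    "BLOCK_ORDERS",
    "Schedule",
    "Equation",
    "EquationResult",
    "TrialOutcome",
    "BlockResult",
    "SessionLog",
    "Responder",
    "generate_equation",
    "run_block",
    "counterbalance",
]

TASK_TYPES = ("simple", "complex")
CONDITIONS = ("chunkable", "nonchunkable")
#: the four within-subject cells, in canonical order
CELLS: Tuple[Tuple[str, str], ...] = tuple(itertools.product(TASK_TYPES, CONDITIONS))
#: the 24 counterbalanced block orders (permutations of the four cells)
BLOCK_ORDERS: Tuple[Tuple[Tuple[str, str], ...], ...] = tuple(itertools.permutations(CELLS))


@dataclass(frozen=True)
class Schedule:
    """Administration constants; timing values are metadata, never waited on."""

    trials_per_length: int = TRIALS_PER_LENGTH
    stop_errors: int = 4
    item_seconds: float = 1.0
    isi_seconds_simple: float = 0.5
    equation_deadline_seconds: float = 3.0


DEFAULT_SCHEDULE = Schedule()


@dataclass(frozen=True)
class Equation:
    """A displayed sum judgment, e.g. ``7 + 2 = 10`` (false)."""

    a: int
    b: int
    stated_sum: int

    @property
    def truth(self) -> bool:
        return self.a + self.b == self.stated_sum

    def __str__(self) -> str:
        return f"{self.a} + {self.b} = {self.stated_sum}"


@dataclass(frozen=True)
class EquationResult:
    equation: Equation
    response: bool
    correct: bool


@dataclass(frozen=True)
class TrialOutcome:
    trial: TrialSpec
    recalled_sequence: Tuple[str, ...]
    correct: bool
    equation_results: Tuple[EquationResult, ...] = ()
    timing: Tuple[Tuple[str, float], ...] = ()

    @property
    def eq_correct_count(self) -> int:
        return sum(r.correct for r in self.equation_results)

    @property
    def eq_total(self) -> int:
        return len(self.equation_results)


@dataclass
class BlockResult:
    task_type: str
    condition: str
    order_position: int
    outcomes: List[TrialOutcome] = field(default_factory=list)


@dataclass
class SessionLog:
    """One participant's four counterbalanced blocks of trial outcomes."""

    participant_id: int
    block_order: int  # index into BLOCK_ORDERS, in [0, 23]
    blocks: List[BlockResult] = field(default_factory=list)

    def validate(self) -> None:
        cells = sorted((b.task_type, b.condition) for b in self.blocks)
        if cells != sorted(CELLS):
            raise ValueError(
                f"participant {self.participant_id}: expected one block per "
                f"task x condition cell, got {cells}"
            )


class Responder(Protocol):
    def recall(self, trial: TrialSpec) -> Sequence[str]: ...

    def judge(self, equation: Equation) -> bool: ...


# false offsets keep the stated sum plausible (unspecified in the procedure)
_FALSE_OFFSETS = (-2, -1, 1, 2)


def generate_equation(rng: np.random.Generator) -> Equation:
    """Operands in 1..9; the stated sum is true with probability one half."""
    a = int(rng.integers(1, 10))
    b = int(rng.integers(1, 10))
    if rng.random() < 0.5:
        stated = a + b
    else:
        stated = a + b + int(rng.choice(_FALSE_OFFSETS))
    return Equation(a, b, stated)


def _trial_timing(task_type: str, length: int, schedule: Schedule) -> Tuple[Tuple[str, float], ...]:
    if task_type == "simple":
        return (
            ("item_seconds", schedule.item_seconds),
            ("isi_seconds", schedule.isi_seconds_simple),
        )
    return (
        ("item_seconds", schedule.item_seconds),
        ("equation_deadline_seconds", schedule.equation_deadline_seconds),
    )


def run_block(
    block: Sequence[TrialSpec],
    task_type: str,
    responder: Responder,
    rng: np.random.Generator,
    schedule: Schedule = DEFAULT_SCHEDULE,
) -> List[TrialOutcome]:
    """Administer trials in order until exhausted or the stop rule fires.

    A trial is correct only when the recalled sequence equals the memoranda
    exactly and in order.  In complex blocks one equation precedes each
    memorandum (so a length-k trial logs k equation judgments).  Once a
    scored length accumulates ``schedule.stop_errors`` errors the block ends;
    practice-trial errors are not counted.  If the responder raises, the
    partial log accumulated so far is attached to the exception.
    """
    if task_type not in TASK_TYPES:
        raise ValueError(f"unknown task_type {task_type!r}")
    outcomes: List[TrialOutcome] = []
    errors_at_length: dict = {}
    for trial in block:
        try:
            eq_results: Tuple[EquationResult, ...] = ()
            if task_type == "complex":
                results = []
                for _ in range(trial.length):
                    eq = generate_equation(rng)
                    response = bool(responder.judge(eq))
                    results.append(EquationResult(eq, response, response == eq.truth))
                eq_results = tuple(results)
            recalled = tuple(responder.recall(trial))
        except Exception as exc:
            exc.partial_log = outcomes  # type: ignore[attr-defined]
            raise
        correct = recalled == trial.memoranda
        outcomes.append(
            TrialOutcome(
                trial=trial,
                recalled_sequence=recalled,
                correct=correct,
                equation_results=eq_results,
                timing=_trial_timing(task_type, trial.length, schedule),
            )
        )
        if not correct and not trial.is_practice:
            errors_at_length[trial.length] = errors_at_length.get(trial.length, 0) + 1
            if errors_at_length[trial.length] >= schedule.stop_errors:
                break
    return outcomes


def counterbalance(n_participants: int) -> List[int]:
    """Cycle the 24 block orders across participants (perfect at n = 96)."""
    if n_participants < 1:
        raise ValueError("need at least one participant")
    return [i % len(BLOCK_ORDERS) for i in range(n_participants)]
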