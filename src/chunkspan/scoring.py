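"""Span scoring, cell statistics, chunking scores, multiplicative algebra.

Each perfectly recalled scored trial is worth 0.25 span units, so with four
trials per list length a fully correct length contributes one unit; length-1
trials count like any other (the scoring arithmetic treats them as scored
despite their warmup role in the procedure).  The *global* chunking score of
a task is the ratio of its chunkable to nonchunkable cell means; *individual*
chunking scores are per-participant ratios, whose mean is a genuinely
different quantity.  The multiplicative-effect record asks whether the
task-type and chunkability benefits combine as a product of ratios over the
least favorable cell (nonchunkable complex span).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import CELLS, CONDITIONS, SessionLog, TASK_TYPES

__all__ = [
    "SpanScore",
    "CellTable",
    "ChunkingReport",
    "span_score",
    "score_sessions",
    "cell_table",
    "chunking_scores",
    "multiplicative_expectation",
    "concurrent_accuracy",
    "reference_cell_table",
    "format_cell_table",
]


@dataclass(frozen=True)
class SpanScore:
    participant_id: int
    task_type: str
    condition: str
    span: float

    def __post_init__(self) -> None:
        if self.span < 0 or round(self.span * 4) != self.span * 4:
            raise ValueError("span must be a nonnegative multiple of 0.25")


@dataclass(frozen=True)
class CellTable:
    """2 x 2 mean/sd/se/n of spans by task type and condition."""

    stats: Dict[Tuple[str, str], Dict[str, float]]

    def mean(self, task_type: str, condition: str) -> float:
        return self.stats[(task_type, condition)]["mean"]

    @classmethod
    def from_means(cls, means: Dict[Tuple[str, str], float],
                   ses: Optional[Dict[Tuple[str, str], float]] = None,
                   n: Optional[int] = None) -> "CellTable":
        stats = {}
        for cell, mean in means.items():
            entry = {"mean": float(mean), "sd": float("nan"),
                     "se": float("nan"), "n": n if n is not None else float("nan")}
            if ses is not None and cell in ses:
                entry["se"] = float(ses[cell])
                if n:
                    entry["sd"] = entry["se"] * np.sqrt(n)
            stats[cell] = entry
        return cls(stats)


@dataclass(frozen=True)
class ChunkingReport:
    global_scores: Dict[str, float]           # task -> ratio of cell means
    individual_scores: Dict[str, Dict[str, float]]  # task -> mean/se/n/n_excluded
    multiplicative: Dict[str, float]


def _is_scored(outcome) -> bool:
    if hasattr(outcome, "trial"):
        return not outcome.trial.is_practice
    return not outcome.is_practice


def span_score(outcomes: Iterable, participant_id: int = -1,
               task_type: str = "", condition: str = "") -> SpanScore:
    """0.25 per perfectly correct scored serial report in one block.

    Practice trials are excluded; every administered scored trial counts,
    including length 1.  Order of trials is irrelevant and the score is
    additive over disjoint sets of correct trials.
    """
    n_correct = sum(1 for out in outcomes if _is_scored(out) and out.correct)
    return SpanScore(participant_id=participant_id, task_type=task_type,
                     condition=condition, span=0.25 * n_correct)


def score_sessions(logs: Sequence[SessionLog]) -> List[SpanScore]:
    """One SpanScore per participant per block across a cohort."""
    scores = []
    for log in logs:
        log.validate()
        for block in log.blocks:
            scores.append(
                span_score(block.outcomes, participant_id=log.participant_id,
                           task_type=block.task_type, condition=block.condition)
            )
    return scores


def cell_table(scores: Sequence[SpanScore]) -> CellTable:
    """Per-cell mean, sd and standard error; every participant needs 4 cells."""
    df = pd.DataFrame(
        {"participant_id": s.participant_id, "task_type": s.task_type,
         "condition": s.condition, "span": s.span} for s in scores
    )
    counts = df.groupby("participant_id").size()
    bad = counts[counts != len(CELLS)]
    if len(bad):
        raise ValueError(
            f"participants missing cells: {sorted(bad.index.tolist())}"
        )
    stats = {}
    for (task, cond), grp in df.groupby(["task_type", "condition"]):
        n = len(grp)
        sd = float(grp["span"].std(ddof=1)) if n > 1 else 0.0
        stats[(task, cond)] = {
            "mean": float(grp["span"].mean()),
            "sd": sd,
            "se": sd / np.sqrt(n) if n else float("nan"),
            "n": n,
        }
    return CellTable(stats)


def chunking_scores(table: CellTable,
                    scores: Optional[Sequence[SpanScore]] = None) -> ChunkingReport:
    """Global (ratio of cell means) and individual (mean of ratios) scores.

    The two paths answer different questions and differ in general.
    Participants with a zero nonchunkable span are excluded from the
    individual ratios (and counted in the report); a zero nonchunkable cell
    mean is an error for the global ratio.
    """
    global_scores = {}
    for task in TASK_TYPES:
        denom = table.mean(task, "nonchunkable")
        if denom == 0:
            raise ValueError(f"zero nonchunkable cell mean for {task} span")
        global_scores[task] = table.mean(task, "chunkable") / denom

    individual: Dict[str, Dict[str, float]] = {}
    if scores is not None:
        by_key = {(s.participant_id, s.task_type, s.condition): s.span for s in scores}
        pids = sorted({s.participant_id for s in scores})
        for task in TASK_TYPES:
            ratios = []
            excluded = 0
            for pid in pids:
                denom = by_key.get((pid, task, "nonchunkable"))
                numer = by_key.get((pid, task, "chunkable"))
                if denom is None or numer is None:
                    continue
                if denom == 0:
                    excluded += 1
                    continue
                ratios.append(numer / denom)
            arr = np.asarray(ratios)
            individual[task] = {
                "mean": float(arr.mean()) if arr.size else float("nan"),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
                "se": float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan"),
                "n": int(arr.size),
                "n_excluded_zero_denominator": excluded,
            }

    return ChunkingReport(
        global_scores=global_scores,
        individual_scores=individual,
        multiplicative=multiplicative_expectation(table),
    )


def multiplicative_expectation(table: CellTable) -> Dict[str, float]:
    """Expected combined benefit if task and chunkability multiply.

    Relative to the least favorable cell (nonchunkable complex):
    ``task_ratio`` is the simple-span benefit, ``chunk_ratio`` the
    chunkability benefit within complex span, their product the expected
    combined increase, and ``observed_ratio`` the increase actually seen in
    the most favorable cell (chunkable simple).
    """
    baseline = table.mean("complex", "nonchunkable")
    if baseline == 0:
        raise ValueError("zero baseline (nonchunkable complex) cell mean")
    task_ratio = table.mean("simple", "nonchunkable") / baseline
    chunk_ratio = table.mean("complex", "chunkable") / baseline
    expected_combined = task_ratio * chunk_ratio
    return {
        "task_ratio": task_ratio,
        "chunk_ratio": chunk_ratio,
        "expected_combined": expected_combined,
        "expected_span": baseline * expected_combined,
        "observed_ratio": table.mean("simple", "chunkable") / baseline,
    }


def concurrent_accuracy(logs: Sequence[SessionLog]) -> Dict[str, object]:
    """Equation-judgment accuracy in complex-span blocks.

    Per-participant proportions averaged by condition, plus a per-length
    accuracy series for trend inspection.
    """
    rows = []
    for log in logs:
        for block in log.blocks:
            if block.task_type != "complex":
                continue
            for out in block.outcomes:
                total = _eq_total(out)
                if total:
                    rows.append(
                        {"participant_id": log.participant_id,
                         "condition": block.condition,
                         "length": _length(out),
                         "eq_correct": _eq_correct(out),
                         "eq_total": total}
                    )
    if not rows:
        raise ValueError("no equation records in the logs")
    df = pd.DataFrame(rows)
    per_participant = (
        df.groupby(["participant_id", "condition"])[["eq_correct", "eq_total"]]
        .sum()
        .assign(accuracy=lambda d: d.eq_correct / d.eq_total)
        .reset_index()
    )
    by_condition = {
        cond: {
            "mean": float(grp["accuracy"].mean()),
            "sd": float(grp["accuracy"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "n": int(len(grp)),
        }
        for cond, grp in per_participant.groupby("condition")
    }
    per_length = (
        df.groupby("length")[["eq_correct", "eq_total"]]
        .sum()
        .assign(accuracy=lambda d: d.eq_correct / d.eq_total)["accuracy"]
        .to_dict()
    )
    return {
        "by_condition": by_condition,
        "per_participant": per_participant,
        "per_length": {int(k): float(v) for k, v in per_length.items()},
    }


def _eq_total(out) -> int:
    return out.eq_total


def _eq_correct(out) -> int:
    return out.eq_correct_count


def _length(out) -> int:
    return out.trial.length if hasattr(out, "trial") else out.length


# ---------------------------------------------------------------------------
# reference table fixture
# ---------------------------------------------------------------------------

def reference_cell_table() -> CellTable:
    """The packaged human reference cell means (printed-table fixture)."""
    text = (
        importlib.resources.files("chunkspan")
        .joinpath("data/reference_cell_means.json")
        .read_text()
    )
    raw = json.loads(text)
    means = {(t, c): raw["means"][t][c] for t in TASK_TYPES for c in CONDITIONS}
    ses = {(t, c): raw["standard_errors"][t][c] for t in TASK_TYPES for c in CONDITIONS}
    return CellTable.from_means(means, ses, n=raw.get("n"))


def format_cell_table(table: CellTable, report: Optional[ChunkingReport] = None) -> str:
    """Human-readable 2 x 2 layout with chunking scores appended."""
    lines = [f"{'':14s}{'Non-Chunkable':>16s}{'Chunkable':>16s}"]
    for task, label in (("simple", "Simple Span"), ("complex", "Complex Span")):
        cells = []
        for cond in ("nonchunkable", "chunkable"):
            s = table.stats[(task, cond)]
            se = s.get("se", float("nan"))
            cells.append(f"{s['mean']:.2f}({se:.2f})")
        row = f"{label:14s}{cells[0]:>16s}{cells[1]:>16s}"
        if report is not None:
            row += f"{report.global_scores[task]:>10.2f}"
        lines.append(row)
    if report is not None:
        lines[0] += f"{'Global':>10s}"
    return "\n".join(lines)
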