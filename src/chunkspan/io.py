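"""Trial-log persistence, run configuration, and the deposited-data loader.

The interchange format is a flat trial-level CSV (UTF-8, comma separator,
header row, "." decimals) with one row per administered trial and a
commented header line recording the generating seed; JSON artifacts are
written with sorted keys.  Logs read back from disk are lightweight
``TrialRecord`` graphs that expose the same fields the scoring and fitting
routines need, so a written-then-read cohort behaves identically to the
in-memory one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .engine import BlockResult, SessionLog, TrialOutcome

__all__ = [
    "SCHEMA_COLUMNS",
    "TrialRecord",
    "RunConfig",
    "logs_to_frame",
    "to_records",
    "write_trial_log",
    "read_trial_log",
    "frame_to_logs",
    "load_deposited",
    "DepositLayoutError",
]

SCHEMA_COLUMNS = [
    "participant_id",
    "block_order_index",
    "task_type",
    "condition",
    "trial_index",
    "is_practice",
    "length",
    "memoranda",
    "lures",
    "complexity",
    "seed",
    "recalled_sequence",
    "correct",
    "eq_correct_count",
    "eq_total",
]

_TOKEN_SEP = ";"


@dataclass(frozen=True)
class TrialRecord:
    """Flat trial-level record mirroring one CSV row."""

    trial_index: int
    is_practice: bool
    length: int
    memoranda: Tuple[str, ...]
    lures: Tuple[str, ...]
    complexity: int
    recalled_sequence: Tuple[str, ...]
    correct: bool
    eq_correct_count: int
    eq_total: int
    metadata: Tuple[Tuple[str, str], ...] = ()


@dataclass
class RunConfig:
    """Reproducibility envelope for a pipeline run."""

    seed: int = 0
    n_participants: int = 94
    out_dir: str = "results"
    verbosity: int = 1
    cohort: Dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _outcome_row(log: SessionLog, block: BlockResult, out) -> dict:
    if isinstance(out, TrialRecord):
        trial_index = out.trial_index
        is_practice = out.is_practice
        length = out.length
        memoranda = out.memoranda
        lures = out.lures
        complexity = out.complexity
    else:
        trial_index = out.trial.trial_id
        is_practice = out.trial.is_practice
        length = out.trial.length
        memoranda = out.trial.memoranda
        lures = out.trial.lures
        complexity = out.trial.complexity
    return {
        "participant_id": log.participant_id,
        "block_order_index": log.block_order,
        "task_type": block.task_type,
        "condition": block.condition,
        "trial_index": trial_index,
        "is_practice": is_practice,
        "length": length,
        "memoranda": _TOKEN_SEP.join(memoranda),
        "lures": _TOKEN_SEP.join(lures),
        "complexity": complexity,
        "recalled_sequence": _TOKEN_SEP.join(out.recalled_sequence),
        "correct": out.correct,
        "eq_correct_count": out.eq_correct_count,
        "eq_total": out.eq_total,
    }


def logs_to_frame(logs: Sequence[SessionLog], seed: Optional[int] = None) -> pd.DataFrame:
    rows = []
    for log in logs:
        for block in log.blocks:
            for out in block.outcomes:
                row = _outcome_row(log, block, out)
                row["seed"] = seed if seed is not None else -1
                rows.append(row)
    return pd.DataFrame(rows, columns=SCHEMA_COLUMNS)


def write_trial_log(logs: Sequence[SessionLog], path: Union[str, Path],
                    seed: Optional[int] = None) -> None:
    """Write a cohort to the trial-log CSV with the seed in the header."""
    df = logs_to_frame(logs, seed=seed)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# chunkspan trial log; seed={seed if seed is not None else -1}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def to_records(logs: Sequence[SessionLog]) -> List[SessionLog]:
    """Deep-copy a cohort into flat TrialRecord graphs (what reading returns)."""
    out = []
    for log in logs:
        blocks = []
        for block in log.blocks:
            records = [
                _row_to_record(_outcome_row(log, block, o)) for o in block.outcomes
            ]
            blocks.append(BlockResult(block.task_type, block.condition,
                                      block.order_position, records))
        out.append(SessionLog(log.participant_id, log.block_order, blocks))
    return out


def _split_tokens(value) -> Tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return ()
    return tuple(str(value).split(_TOKEN_SEP))


def _row_to_record(row: dict) -> TrialRecord:
    return TrialRecord(
        trial_index=int(row["trial_index"]),
        is_practice=bool(row["is_practice"]),
        length=int(row["length"]),
        memoranda=_split_tokens(row["memoranda"]),
        lures=_split_tokens(row["lures"]),
        complexity=int(row["complexity"]),
        recalled_sequence=_split_tokens(row["recalled_sequence"]),
        correct=bool(row["correct"]),
        eq_correct_count=int(row["eq_correct_count"]),
        eq_total=int(row["eq_total"]),
    )


def frame_to_logs(df: pd.DataFrame) -> List[SessionLog]:
    """Group a schema-conforming frame into SessionLog/TrialRecord graphs."""
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log is missing columns: {missing}")
    unknown = [c for c in df.columns if c not in SCHEMA_COLUMNS]
    if unknown:
        raise ValueError(f"trial log has unknown columns: {unknown}")
    logs = []
    for pid, pgrp in df.groupby("participant_id", sort=True):
        orders = pgrp["block_order_index"].unique()
        if len(orders) != 1:
            raise ValueError(f"participant {pid}: inconsistent block_order_index")
        cells = pgrp[["task_type", "condition"]].drop_duplicates()
        log = SessionLog(participant_id=int(pid), block_order=int(orders[0]))
        seen = set()
        for _, (task, cond) in cells.iterrows():
            if (task, cond) in seen:
                raise ValueError(f"participant {pid}: duplicated cell {(task, cond)}")
            seen.add((task, cond))
            bgrp = pgrp[(pgrp.task_type == task) & (pgrp.condition == cond)]
            if bgrp["trial_index"].duplicated().any():
                raise ValueError(
                    f"participant {pid}: duplicated {(task, cond)} cell "
                    "(repeated trial indices)"
                )
            bgrp = bgrp.sort_values("trial_index")
            records = [_row_to_record(row) for row in bgrp.to_dict("records")]
            log.blocks.append(BlockResult(task, cond, len(log.blocks), records))
        log.validate()
        logs.append(log)
    return logs


def read_trial_log(path: Union[str, Path]) -> List[SessionLog]:
    """Read and validate a trial-log CSV written by :func:`write_trial_log`.

    Malformed rows are reported with their file line numbers; a file with a
    header but no rows yields an empty list with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty trial log")
        return []
    if df.empty:
        warnings.warn(f"{path}: empty trial log")
        return []
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    unknown = [c for c in df.columns if c not in SCHEMA_COLUMNS]
    if missing or unknown:
        raise ValueError(
            f"{path}: schema mismatch; missing columns {missing}, unknown columns {unknown}"
        )
    bad_lines = []
    for idx, row in df.iterrows():
        try:
            _row_to_record(row.to_dict())
        except (ValueError, TypeError, KeyError) as exc:
            bad_lines.append((int(idx) + 3, str(exc)))  # +1 header +1 comment +1-based
    if bad_lines:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad_lines[:5])
        raise ValueError(f"{path}: {len(bad_lines)} malformed rows ({detail})")
    return frame_to_logs(df)


# ---------------------------------------------------------------------------
# deposited-data loader
# ---------------------------------------------------------------------------

class DepositLayoutError(ValueError):
    """The deposited file's layout does not match the column-mapping config."""


def _default_mapping_path() -> Path:
    import importlib.resources

    return Path(str(importlib.resources.files("chunkspan").joinpath("data/deposit_mapping.yaml")))


def load_deposited(path: Union[str, Path],
                   mapping_path: Union[str, Path, None] = None) -> List[SessionLog]:
    """Load a locally downloaded trial-level deposit into SessionLogs.

    The deposit's internal layout is decoupled from this package through a
    user-editable YAML mapping (``data/deposit_mapping.yaml`` by default)
    giving, for each schema column, the source column name and optional
    value translations.  Unmapped source columns are preserved as metadata
    on each record.  A missing file raises ``FileNotFoundError``; a layout
    that does not match the mapping raises :class:`DepositLayoutError`
    pointing at the mapping config.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"deposit file not found: {path}")
    mapping_file = Path(mapping_path) if mapping_path else _default_mapping_path()
    mapping = yaml.safe_load(mapping_file.read_text())
    columns: Dict[str, str] = mapping.get("columns", {})
    translations: Dict[str, Dict] = mapping.get("values", {})
    defaults: Dict[str, object] = mapping.get("defaults", {})

    df = pd.read_csv(path, comment="#")
    missing_src = [src for src in columns.values() if src not in df.columns]
    if missing_src:
        raise DepositLayoutError(
            f"{path}: source columns {missing_src} not found; "
            f"edit the column mapping at {mapping_file}"
        )
    out = pd.DataFrame()
    for target, src in columns.items():
        series = df[src]
        if target in translations:
            series = series.map(translations[target])
            if series.isna().any():
                bad = sorted(df[src][series.isna()].unique().tolist())
                raise DepositLayoutError(
                    f"{path}: untranslatable values {bad!r} for {target!r}; "
                    f"edit the value map at {mapping_file}"
                )
        out[target] = series
    for target, value in defaults.items():
        if target not in out.columns:
            out[target] = value
    for col in SCHEMA_COLUMNS:
        if col not in out.columns:
            raise DepositLayoutError(
                f"{path}: no mapping or default produces column {col!r}; "
                f"edit {mapping_file}"
            )
    logs = frame_to_logs(out[SCHEMA_COLUMNS])
    # unmapped source columns preserved as per-record metadata
    extra_cols = [c for c in df.columns if c not in columns.values()]
    if extra_cols:
        meta_by_key = {}
        for i in range(len(df)):
            key = (int(out["participant_id"].iloc[i]), str(out["task_type"].iloc[i]),
                   str(out["condition"].iloc[i]), int(out["trial_index"].iloc[i]))
            meta_by_key[key] = tuple((c, str(df[c].iloc[i])) for c in extra_cols)
        for log in logs:
            for block in log.blocks:
                for j, rec in enumerate(block.outcomes):
                    key = (log.participant_id, block.task_type, block.condition,
                           rec.trial_index)
                    meta = meta_by_key.get(key, ())
                    block.outcomes[j] = TrialRecord(**{**asdict(rec), "metadata": meta})
    return logs
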