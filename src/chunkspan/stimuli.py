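"""Serial-list construction for the chunkable / non-chunkable conditions.

Lists of length 1..8 are drawn from an 8-object space built, per trial, from
a random pair of shapes (among eight), a random pair of colors (among eight)
and the fixed large/small size pair.  Chunkable lists use the most
compressible category structures at each length, presented in a hierarchical
serial order that makes the regularity easy to discover; non-chunkable lists
use the least compressible structures that admit an ordering in which no two
consecutive objects share more than one feature (Hamming distance >= 2), with
the most incompressible structures alternating with less incompressible ones
across the four trials of a length.

Template structures are abstract (bit patterns); each trial instantiates a
template through a random relabeling — which abstract dimension plays which
concrete role, and which value is which — that preserves complexity exactly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .complexity import (
    Bits,
    CategorySet,
    DEFAULT_SPACE,
    Dimension,
    FeatureSpace,
    complement,
    feature_distance,
    minimal_complexity,
)

__all__ = [
    "SHAPE_NAMES",
    "COLOR_NAMES",
    "SIZE_NAMES",
    "SIZE_PIXELS",
    "StructureTemplate",
    "DimensionAssignment",
    "TrialSpec",
    "sample_assignment",
    "build_structure_library",
    "instantiate",
    "build_block",
    "possible_object_set_counts",
    "library_json",
]

SHAPE_NAMES = ("square", "triangle", "circle", "cross", "star", "diamond", "pentagon", "heart")
COLOR_NAMES = ("blue", "red", "green", "purple", "yellow", "orange", "black", "white")
SIZE_NAMES = ("small", "large")
#: display sizes recorded as metadata only (no rendering in this pipeline)
SIZE_PIXELS = {"small": 140, "large": 280}

N_DIMS = 3
MAX_LENGTH = 8
TRIALS_PER_LENGTH = 4
PRACTICE_LENGTHS = (1, 1, 2)


@dataclass(frozen=True)
class StructureTemplate:
    """An ordered abstract list (bit patterns) with its nominal complexity."""

    ordered_bits: Tuple[Bits, ...]
    condition: str                     # "chunkable" | "nonchunkable"
    nominal_complexity: int
    incompressibility_rank: Optional[str] = None  # "most" | "less" (nonchunkable)

    def __post_init__(self) -> None:
        if self.condition not in ("chunkable", "nonchunkable"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(set(self.ordered_bits)) != len(self.ordered_bits):
            raise ValueError("duplicate objects in a serial list")
        if not 1 <= len(self.ordered_bits) <= MAX_LENGTH:
            raise ValueError("list length must be in 1..8")
        if self.condition == "nonchunkable":
            for a, b in zip(self.ordered_bits, self.ordered_bits[1:]):
                if feature_distance(a, b) < 2:
                    raise ValueError(
                        "nonchunkable constraint violated: consecutive objects "
                        f"{a} and {b} share more than one feature"
                    )

    @property
    def length(self) -> int:
        return len(self.ordered_bits)


@dataclass(frozen=True)
class DimensionAssignment:
    """Concrete feature values for one trial's 8-object space."""

    shapes: Tuple[str, str]
    colors: Tuple[str, str]
    sizes: Tuple[str, str] = SIZE_NAMES

    def __post_init__(self) -> None:
        if len(set(self.shapes)) != 2 or len(set(self.colors)) != 2:
            raise ValueError("shape and color pairs must each be distinct")

    def space(self) -> FeatureSpace:
        return FeatureSpace(
            (
                Dimension("shape", self.shapes),
                Dimension("color", self.colors),
                Dimension("size", self.sizes),
            )
        )


@dataclass(frozen=True)
class TrialSpec:
    """One fully concrete trial: memoranda in order plus the response screen."""

    template: StructureTemplate
    assignment: DimensionAssignment
    memoranda: Tuple[str, ...]          # concrete tokens shape:color:size, in order
    lures: Tuple[str, ...]              # complement objects (unordered canonical)
    response_screen: Tuple[str, ...]    # all 8 objects, positions randomized
    trial_id: int
    is_practice: bool = False

    @property
    def length(self) -> int:
        return len(self.memoranda)

    @property
    def condition(self) -> str:
        return self.template.condition

    @property
    def complexity(self) -> int:
        return self.template.nominal_complexity


def possible_object_set_counts() -> Dict[str, int]:
    """Number of distinct 8-object spaces the feature vocabulary generates.

    With eight shapes, eight colors and one fixed size pair the natural
    unordered count is C(8,2) * C(8,2) = 784; treating one dimension's value
    pair as ordered doubles it to 1568.  Both conventions are reported.
    """
    unordered = 28 * 28
    return {"unordered_pairs": unordered, "one_dimension_ordered": 2 * unordered}


# ---------------------------------------------------------------------------
# structure libraries
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _complexity_by_mask() -> Dict[frozenset, int]:
    space = DEFAULT_SPACE
    out = {}
    for r in range(0, space.n_objects + 1):
        for sub in itertools.combinations(space.all_objects(), r):
            s = CategorySet.from_members(space, sub)
            out[frozenset(sub)] = minimal_complexity(s).minimal_literals
    return out


def _hierarchical_order(members: Sequence[Bits]) -> Tuple[Bits, ...]:
    """Serial order making the structure's regularity easy to discover.

    Dimensions are ranked by diagnosticity (how unbalanced the feature is
    within the set, constant features first), then members are sorted
    lexicographically under that ranking: the list comes out grouped by the
    most diagnostic varying feature with a consistent value order inside
    each group.
    """
    members = list(members)
    L = len(members)

    def imbalance(d: int) -> float:
        ones = sum(m[d] for m in members)
        return abs(ones - L / 2)

    dim_order = sorted(range(N_DIMS), key=lambda d: (-imbalance(d), d))
    return tuple(sorted(members, key=lambda m: tuple(m[d] for d in dim_order)))


def _valid_orders(members: Sequence[Bits]):
    """All serial orders with consecutive Hamming distance >= 2."""
    for perm in itertools.permutations(sorted(members)):
        if all(feature_distance(a, b) >= 2 for a, b in zip(perm, perm[1:])):
            yield perm


def _incompressible_order(members: Sequence[Bits]) -> Optional[Tuple[Bits, ...]]:
    """Admissible order maximizing summed inter-item distance (deterministic)."""
    best: Optional[Tuple[Bits, ...]] = None
    best_score = -1
    for perm in _valid_orders(members):
        score = sum(feature_distance(a, b) for a, b in zip(perm, perm[1:]))
        if score > best_score:  # ties resolved by first (lexicographic) hit
            best, best_score = perm, score
    return best


@lru_cache(maxsize=32)
def build_structure_library(length: int, condition: str) -> Tuple[StructureTemplate, ...]:
    """All admissible abstract templates for one length and condition.

    Chunkable: the minimum-complexity subsets of the given size, in
    hierarchical serial order.  Nonchunkable: subsets admitting an ordering
    with every consecutive distance >= 2, restricted to the top two distinct
    complexity values and tagged ``most`` / ``less``; at lengths 7 and 8 all
    subsets share a single forced complexity, so both rank tags draw from it
    and only serial order distinguishes the conditions.
    """
    if not 1 <= length <= MAX_LENGTH:
        raise ValueError("length must be in 1..8")
    cx = _complexity_by_mask()
    objects = DEFAULT_SPACE.all_objects()
    subsets = [frozenset(s) for s in itertools.combinations(objects, length)]

    if condition == "chunkable":
        cmin = min(cx[s] for s in subsets)
        return tuple(
            StructureTemplate(_hierarchical_order(sorted(s)), "chunkable", cx[s])
            for s in sorted(subsets, key=lambda s: tuple(sorted(s)))
            if cx[s] == cmin
        )
    if condition != "nonchunkable":
        raise ValueError(f"unknown condition {condition!r}")

    orderable = {}
    for s in subsets:
        order = _incompressible_order(tuple(s))
        if order is not None:
            orderable[s] = order
    if not orderable:
        raise ValueError(
            f"no length-{length} subset admits consecutive feature distance >= 2"
        )
    values = sorted({cx[s] for s in orderable}, reverse=True)
    ranks = {"most": values[0], "less": values[1] if len(values) > 1 else values[0]}
    templates = []
    for rank in ("most", "less"):
        for s in sorted(orderable, key=lambda s: tuple(sorted(s))):
            if cx[s] == ranks[rank]:
                templates.append(
                    StructureTemplate(orderable[s], "nonchunkable", cx[s], rank)
                )
    return tuple(templates)


def library_json(lengths: Sequence[int] = range(1, MAX_LENGTH + 1)) -> str:
    """Structure libraries for both conditions as a JSON document."""
    entries = []
    for length in lengths:
        for condition in ("chunkable", "nonchunkable"):
            for t in build_structure_library(length, condition):
                entries.append(
                    {
                        "length": t.length,
                        "condition": t.condition,
                        "ordered_bits": ["".join(map(str, b)) for b in t.ordered_bits],
                        "nominal_complexity": t.nominal_complexity,
                        "rank": t.incompressibility_rank,
                    }
                )
    return json.dumps(entries, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# concrete trials
# ---------------------------------------------------------------------------

def sample_assignment(rng: np.random.Generator) -> DimensionAssignment:
    """Uniformly draw the trial's concrete feature pairs (sizes are fixed)."""
    shapes = tuple(rng.choice(len(SHAPE_NAMES), size=2, replace=False))
    colors = tuple(rng.choice(len(COLOR_NAMES), size=2, replace=False))
    return DimensionAssignment(
        shapes=(SHAPE_NAMES[shapes[0]], SHAPE_NAMES[shapes[1]]),
        colors=(COLOR_NAMES[colors[0]], COLOR_NAMES[colors[1]]),
    )


def _relabel(bits: Bits, dim_perm: Sequence[int], flips: Sequence[int]) -> Bits:
    """Map abstract dims onto concrete roles with per-dimension polarity flips."""
    out = [0] * N_DIMS
    for abstract_d, concrete_d in enumerate(dim_perm):
        out[concrete_d] = bits[abstract_d] ^ flips[concrete_d]
    return tuple(out)


def instantiate(
    template: StructureTemplate,
    assignment: DimensionAssignment,
    rng: np.random.Generator,
    trial_id: int = 0,
    is_practice: bool = False,
) -> TrialSpec:
    """Concrete trial from an abstract template under a random relabeling.

    A random bijection decides which abstract dimension plays which concrete
    role (shape/color/size) and which value of each pair is which, so the
    category structure — and therefore its complexity and all pairwise
    distances — is preserved exactly.  The response screen holds the k
    memoranda and the 8 - k complement lures in random positions.
    """
    space = assignment.space()
    dim_perm = tuple(rng.permutation(N_DIMS))
    flips = tuple(rng.integers(0, 2, size=N_DIMS))
    ordered = tuple(_relabel(b, dim_perm, flips) for b in template.ordered_bits)
    memoranda = tuple(space.describe(b) for b in ordered)
    lure_bits = sorted(set(space.all_objects()) - set(ordered))
    lures = tuple(space.describe(b) for b in lure_bits)
    screen = list(memoranda) + list(lures)
    screen = tuple(screen[i] for i in rng.permutation(len(screen)))
    return TrialSpec(
        template=template,
        assignment=assignment,
        memoranda=memoranda,
        lures=lures,
        response_screen=screen,
        trial_id=trial_id,
        is_practice=is_practice,
    )


def build_block(
    condition: str,
    task_type: str,
    rng: np.random.Generator,
) -> List[TrialSpec]:
    """Full trial schedule for one block, before any stop rule.

    Three practice trials (lengths 1, 1, 2) are prepended, then lengths
    ascend 1..8 with four trials per length.  In nonchunkable blocks the four
    trials of a length alternate most- and less-incompressible templates
    (most first).  Each trial gets a fresh random dimension assignment,
    rejecting an exact repeat of the previous trial's, and a fresh random
    relabeling of the template.
    """
    if task_type not in ("simple", "complex"):
        raise ValueError(f"unknown task_type {task_type!r}")
    schedule: List[Tuple[int, bool, int]] = []  # (length, is_practice, slot)
    for i, plen in enumerate(PRACTICE_LENGTHS):
        schedule.append((plen, True, i))
    for length in range(1, MAX_LENGTH + 1):
        for slot in range(TRIALS_PER_LENGTH):
            schedule.append((length, False, slot))

    trials: List[TrialSpec] = []
    prev_assignment: Optional[DimensionAssignment] = None
    for trial_id, (length, is_practice, slot) in enumerate(schedule):
        pool = build_structure_library(length, condition)
        if condition == "nonchunkable":
            rank = "most" if slot % 2 == 0 else "less"
            pool = tuple(t for t in pool if t.incompressibility_rank == rank)
        template = pool[rng.integers(0, len(pool))]
        while True:  # proactive-interference control: never repeat a space
            assignment = sample_assignment(rng)
            if assignment != prev_assignment:
                break
        prev_assignment = assignment
        trials.append(
            instantiate(template, assignment, rng, trial_id=trial_id, is_practice=is_practice)
        )
    return trials
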