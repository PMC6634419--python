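"""Boolean compressibility of category sets over binary feature dimensions.

A category set is a subset of the 2**D objects definable over D two-valued
dimensions (here typically shape, color, size; D = 3).  Its *compressibility*
is operationalized as the minimal number of feature literals in an and/or/not
formula whose extension is exactly the set.  Negation is free (costs no
literals) and may apply to subformulas, so a category and its complement
always have the same complexity (*parity*).  The verbatim description —
listing every feature of every member — has length D x |members| and upper
bounds the minimum.

The exhaustive search is a dynamic program over formula extensions: any
formula with k >= 2 literals is, after stripping negations, a conjunction or
disjunction of two subformulas with a + b = k literals, so iterating k upward
and combining previously reached extensions (closed under complementation,
since NOT is free) visits every extension at its minimal literal count.
At D = 3 all 256 extensions are resolved in milliseconds.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence, Tuple, Union

Bits = Tuple[int, ...]

__all__ = [
    "Dimension",
    "FeatureSpace",
    "CategorySet",
    "Formula",
    "Literal",
    "Not",
    "And",
    "Or",
    "TRUE",
    "FALSE",
    "ComplexityResult",
    "feature_distance",
    "verbatim_length",
    "complement",
    "minimal_complexity",
    "catalog",
    "catalog_json",
    "DEFAULT_SPACE",
]


# ---------------------------------------------------------------------------
# feature space and category sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dimension:
    """One binary stimulus dimension, e.g. color with values (white, black)."""

    name: str
    values: Tuple[str, str]

    def __post_init__(self) -> None:
        if len(set(self.values)) != 2:
            raise ValueError(f"dimension {self.name!r} needs 2 distinct values")


@dataclass(frozen=True)
class FeatureSpace:
    """An ordered collection of binary dimensions defining 2**D objects."""

    dimensions: Tuple[Dimension, ...]

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise ValueError("need at least one dimension")
        names = [d.name for d in self.dimensions]
        if len(set(names)) != len(names):
            raise ValueError("dimension names must be distinct")

    @property
    def n_dims(self) -> int:
        return len(self.dimensions)

    @property
    def n_objects(self) -> int:
        return 1 << self.n_dims

    def all_objects(self) -> Tuple[Bits, ...]:
        return tuple(itertools.product((0, 1), repeat=self.n_dims))

    def describe(self, bits: Bits) -> str:
        """Concrete token for an object, e.g. ``square:black:small``."""
        self.validate_bits(bits)
        return ":".join(d.values[b] for d, b in zip(self.dimensions, bits))

    def validate_bits(self, bits: Bits) -> None:
        if len(bits) != self.n_dims or any(b not in (0, 1) for b in bits):
            raise ValueError(f"object {bits!r} does not fit a {self.n_dims}-dimension space")


#: the study's canonical abstract space (two shapes, two colors, two sizes)
DEFAULT_SPACE = FeatureSpace(
    (
        Dimension("shape", ("square", "triangle")),
        Dimension("color", ("white", "black")),
        Dimension("size", ("small", "large")),
    )
)


@dataclass(frozen=True)
class CategorySet:
    """A subset of a feature space; the unit compressibility is computed on."""

    space: FeatureSpace
    members: frozenset

    def __post_init__(self) -> None:
        for bits in self.members:
            self.space.validate_bits(bits)

    @classmethod
    def from_members(cls, space: FeatureSpace, members: Iterable[Bits]) -> "CategorySet":
        return cls(space, frozenset(tuple(m) for m in members))

    def __len__(self) -> int:
        return len(self.members)

    def mask(self) -> int:
        """Extension encoded as a bitmask over the 2**D objects."""
        m = 0
        for bits in self.members:
            m |= 1 << _index(bits)
        return m


def _index(bits: Bits) -> int:
    i = 0
    for d, b in enumerate(bits):
        i |= b << d
    return i


def _bits(index: int, n_dims: int) -> Bits:
    return tuple((index >> d) & 1 for d in range(n_dims))


def feature_distance(a: Bits, b: Bits) -> int:
    """Hamming distance between two objects of the same space."""
    if len(a) != len(b):
        raise ValueError("objects belong to spaces of different dimensionality")
    return sum(x != y for x, y in zip(a, b))


def verbatim_length(catset: CategorySet) -> int:
    """Length of the uncompressed description: D features per member."""
    if not catset.members:
        raise ValueError("verbatim description undefined for an empty set")
    return catset.space.n_dims * len(catset.members)


def complement(catset: CategorySet) -> CategorySet:
    """Space minus members (the lure set of a trial's response screen)."""
    members = frozenset(catset.space.all_objects()) - catset.members
    return CategorySet(catset.space, members)


# ---------------------------------------------------------------------------
# formulas
# ---------------------------------------------------------------------------

class Formula:
    """Node of an and/or/not expression tree over dimension literals."""

    __slots__ = ()

    @property
    def literal_count(self) -> int:
        raise NotImplementedError

    def evaluate(self, bits: Bits) -> bool:
        raise NotImplementedError

    def extension(self, space: FeatureSpace) -> frozenset:
        return frozenset(b for b in space.all_objects() if self.evaluate(b))

    def serialize(self, space: Optional[FeatureSpace] = None) -> str:
        """Plain-text form: literals as dim=value, operators & | !, parens."""
        return self._ser(space, top=True)

    def _ser(self, space: Optional[FeatureSpace], top: bool = False) -> str:
        raise NotImplementedError

    # canonical key: space-independent serialization, used for tie-breaking
    def key(self) -> str:
        return self._ser(None, top=True)

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.key()!r})"


class _Constant(Formula):
    __slots__ = ("value",)

    def __init__(self, value: bool):
        self.value = value

    @property
    def literal_count(self) -> int:
        return 0

    def evaluate(self, bits: Bits) -> bool:
        return self.value

    def _ser(self, space, top=False) -> str:
        return "TRUE" if self.value else "FALSE"


TRUE = _Constant(True)
FALSE = _Constant(False)


class Literal(Formula):
    __slots__ = ("dim", "polarity")

    def __init__(self, dim: int, polarity: int):
        if polarity not in (0, 1):
            raise ValueError("polarity must be 0 or 1")
        self.dim = dim
        self.polarity = polarity

    @property
    def literal_count(self) -> int:
        return 1

    def evaluate(self, bits: Bits) -> bool:
        return bits[self.dim] == self.polarity

    def _ser(self, space, top=False) -> str:
        if space is None:
            return f"d{self.dim}={self.polarity}"
        dim = space.dimensions[self.dim]
        return f"{dim.name}={dim.values[self.polarity]}"


class Not(Formula):
    __slots__ = ("child",)

    def __new__(cls, child: Formula):
        if isinstance(child, Not):          # eliminate double negation
            return child.child
        if isinstance(child, Literal):      # flip polarity instead of wrapping
            return Literal(child.dim, 1 - child.polarity)
        if isinstance(child, _Constant):
            return FALSE if child.value else TRUE
        self = object.__new__(cls)
        self.child = child
        return self

    @property
    def literal_count(self) -> int:
        return self.child.literal_count

    def evaluate(self, bits: Bits) -> bool:
        return not self.child.evaluate(bits)

    def _ser(self, space, top=False) -> str:
        return f"!({self.child._ser(space)})"


class _BinOp(Formula):
    __slots__ = ("children",)
    op = ""

    def __init__(self, *children: Formula):
        # commutative: canonical order by key
        self.children = tuple(sorted(children, key=lambda f: f.key()))
        if len(self.children) < 2:
            raise ValueError("need at least two children")

    @property
    def literal_count(self) -> int:
        return sum(c.literal_count for c in self.children)

    def _ser(self, space, top=False) -> str:
        parts = []
        for c in self.children:
            s = c._ser(space)
            if self._needs_parens(c):
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)

    def _needs_parens(self, child: Formula) -> bool:
        raise NotImplementedError


class And(_BinOp):
    __slots__ = ()
    op = "&"

    def evaluate(self, bits: Bits) -> bool:
        return all(c.evaluate(bits) for c in self.children)

    def _needs_parens(self, child: Formula) -> bool:
        return isinstance(child, Or)


class Or(_BinOp):
    __slots__ = ()
    op = "|"

    def evaluate(self, bits: Bits) -> bool:
        return any(c.evaluate(bits) for c in self.children)

    def _needs_parens(self, child: Formula) -> bool:
        return False  # | binds loosest; & children are unambiguous


@dataclass(frozen=True)
class ComplexityResult:
    """Minimal literal count with a witness formula whose extension is the set."""

    minimal_literals: int
    witness: Formula
    method: str  # "exhaustive" | "heuristic"


# ---------------------------------------------------------------------------
# minimal-formula search
# ---------------------------------------------------------------------------

def _literal_mask(dim: int, polarity: int, n_dims: int) -> int:
    m = 0
    for i in range(1 << n_dims):
        if (i >> dim) & 1 == polarity:
            m |= 1 << i
    return m


@lru_cache(maxsize=8)
def _build_catalog(n_dims: int, beam: Optional[int]) -> dict:
    """Map every reachable extension mask to (minimal literals, witness).

    Iterative deepening on literal count; level k combines first-achieved
    extensions from levels a + b = k under AND/OR, with free complementation.
    ``beam`` caps the number of extensions carried per level (heuristic mode);
    ``None`` is exhaustive.  Ties within a level are broken by the smallest
    canonical serialization of the candidate formula.
    """
    n_states = 1 << (1 << n_dims)
    full = n_states - 1
    best: dict = {full: (0, TRUE), 0: (0, FALSE)}
    levels: dict = {0: [full, 0]}
    max_k = n_dims * (1 << n_dims)  # verbatim bound of the largest set

    k = 0
    while len(best) < n_states and k < max_k:
        k += 1
        cand: dict = {}

        def offer(mask: int, f: Formula) -> None:
            if mask in best:
                return
            old = cand.get(mask)
            if old is None or f.key() < old.key():
                cand[mask] = f

        if k == 1:
            for d in range(n_dims):
                for pol in (0, 1):
                    offer(_literal_mask(d, pol, n_dims), Literal(d, pol))
        for a in range(1, k // 2 + 1):
            b = k - a
            for m1 in levels.get(a, ()):
                for m2 in levels.get(b, ()):
                    f1, f2 = best[m1][1], best[m2][1]
                    offer(m1 & m2, And(f1, f2))
                    offer(m1 | m2, Or(f1, f2))
        # free NOT: the complement of anything reached now is also reached now
        for mask, f in list(cand.items()):
            offer(full ^ mask, Not(f))

        new_masks = sorted(cand)
        if beam is not None and len(new_masks) > beam:
            new_masks = new_masks[:beam]
        for m in new_masks:
            best[m] = (k, cand[m])
        levels[k] = new_masks
    return best


def _dnf_fallback(catset: CategorySet) -> Formula:
    """Verbatim disjunctive normal form: one full conjunction per member."""
    terms = []
    for bits in sorted(catset.members):
        lits = [Literal(d, b) for d, b in enumerate(bits)]
        terms.append(And(*lits) if len(lits) > 1 else lits[0])
    return Or(*terms) if len(terms) > 1 else terms[0]


def minimal_complexity(catset: CategorySet, mode: str = "exhaustive",
                       beam: int = 1024) -> ComplexityResult:
    """Minimal number of feature literals describing ``catset`` exactly.

    ``mode="exhaustive"`` guarantees the global minimum (intended for D <= 3,
    where the whole catalog is built once and cached).  ``mode="heuristic"``
    caps the search frontier at ``beam`` extensions per literal level and
    falls back to the verbatim disjunctive normal form for any extension the
    capped search misses, so its result always satisfies
    ``minimal_literals <= verbatim_length``.  The empty set and the full
    space get complexity 0 (contradiction / tautology witness).
    """
    if mode not in ("exhaustive", "heuristic"):
        raise ValueError(f"unknown mode {mode!r}")
    n_dims = catset.space.n_dims
    if mode == "exhaustive" and n_dims > 4:
        raise ValueError("exhaustive search is only supported for D <= 4; use heuristic mode")
    cat = _build_catalog(n_dims, None if mode == "exhaustive" else beam)
    entry = cat.get(catset.mask())
    if entry is None:  # only possible under a binding beam
        witness = _dnf_fallback(catset)
        return ComplexityResult(witness.literal_count, witness, "heuristic")
    k, witness = entry
    return ComplexityResult(k, witness, mode)


def catalog(space: FeatureSpace) -> dict:
    """Minimal complexity of every subset of ``space`` (mask -> result)."""
    cat = _build_catalog(space.n_dims, None)
    return {mask: ComplexityResult(k, f, "exhaustive") for mask, (k, f) in cat.items()}


def catalog_json(space: FeatureSpace) -> str:
    """JSON catalog of all category sets of a space with minimal witnesses.

    Each entry lists the member bit strings, the minimal literal count and the
    witness serialization; used as a fixture by the stimulus designer.
    """
    entries = []
    n = space.n_dims
    for mask, res in sorted(catalog(space).items()):
        members = ["".join(map(str, _bits(i, n))) for i in range(1 << n) if (mask >> i) & 1]
        entries.append(
            {
                "members": members,
                "minimal_literals": res.minimal_literals,
                "witness": res.witness.serialize(space),
            }
        )
    return json.dumps(entries, sort_keys=True, indent=1)
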