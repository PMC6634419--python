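"""Chunkable / non-chunkable list construction and trial instantiation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chunkspan.complexity import (
    CategorySet,
    complement,
    feature_distance,
    minimal_complexity,
)
from chunkspan.stimuli import (
    DimensionAssignment,
    build_block,
    build_structure_library,
    instantiate,
    possible_object_set_counts,
    sample_assignment,
)


def tokens_to_bits(tokens, space):
    out = []
    for tok in tokens:
        vals = tok.split(":")
        out.append(tuple(dim.values.index(v) for dim, v in zip(space.dimensions, vals)))
    return out


# ---------------------------------------------------------------------------
# dimension assignments
# ---------------------------------------------------------------------------

def test_sample_assignment_invariants_and_seed_dependence():
    a = sample_assignment(np.random.default_rng(1))
    b = sample_assignment(np.random.default_rng(2))
    assert len(set(a.shapes)) == 2 and len(set(a.colors)) == 2
    assert a.sizes == ("small", "large")
    assert (a.shapes, a.colors) != (b.shapes, b.colors)


def test_sample_assignment_is_uniform_over_shapes():
    """Each of the 8 shapes should appear in about 1/4 of assignments."""
    rng = np.random.default_rng(12345)
    n = 10_000
    counts = {}
    for _ in range(n):
        for s in sample_assignment(rng).shapes:
            counts[s] = counts.get(s, 0) + 1
    p = 0.25
    se = np.sqrt(p * (1 - p) / n)
    for shape, c in counts.items():
        assert abs(c / n - p) < 3 * se, shape
    assert len(counts) == 8


def test_invalid_assignment_rejected():
    with pytest.raises(ValueError):
        DimensionAssignment(shapes=("square", "square"), colors=("red", "blue"))


# ---------------------------------------------------------------------------
# structure libraries
# ---------------------------------------------------------------------------

def test_chunkable_length4_is_one_feature_and_grouped():
    lib = build_structure_library(4, "chunkable")
    assert all(t.nominal_complexity == 1 for t in lib)
    assert len(lib) == 6  # the six half-spaces
    for t in lib:
        # hierarchically grouped: first two items share the leading varying
        # feature value, last two share the other
        varying = [d for d in range(3) if len({b[d] for b in t.ordered_bits}) == 2]
        lead = varying[0]
        vals = [b[lead] for b in t.ordered_bits]
        assert vals == sorted(vals)


def test_nonchunkable_length3_ranks_are_8_and_5():
    lib = build_structure_library(3, "nonchunkable")
    most = {t.nominal_complexity for t in lib if t.incompressibility_rank == "most"}
    less = {t.nominal_complexity for t in lib if t.incompressibility_rank == "less"}
    assert most == {8}
    assert less == {5}


def test_odd_parity_four_set_is_admissible_nonchunkable():
    """The 4-set with an odd number of 1-bits (all pairwise distances even)
    is the most incompressible length-4 structure and satisfies the
    consecutive-distance constraint."""
    lib = build_structure_library(4, "nonchunkable")
    most = [t for t in lib if t.incompressibility_rank == "most"]
    assert {t.nominal_complexity for t in most} == {10}
    parities = {tuple(sorted(t.ordered_bits)) for t in most}
    odd = tuple(sorted(b for b in [(0, 0, 1), (0, 1, 0), (1, 0, 0), (1, 1, 1)]))
    assert odd in parities
    for t in most:
        for a, b in zip(t.ordered_bits, t.ordered_bits[1:]):
            assert feature_distance(a, b) >= 2


def test_condition_separation_where_distinct_subsets_exist():
    """For lengths 2..6, every chunkable structure is strictly more
    compressible than every admissible nonchunkable structure."""
    for length in range(2, 7):
        cmax = max(t.nominal_complexity for t in build_structure_library(length, "chunkable"))
        nmin = min(t.nominal_complexity for t in build_structure_library(length, "nonchunkable"))
        assert cmax < nmin, length


def test_length_7_and_8_differ_only_in_serial_order():
    """At lengths 7 and 8 complexity is forced (parity: every 7-subset costs
    3, the full space 0), so the conditions contrast only in ordering."""
    for length, forced in ((7, 3), (8, 0)):
        ch = build_structure_library(length, "chunkable")
        nc = build_structure_library(length, "nonchunkable")
        assert {t.nominal_complexity for t in ch} == {forced}
        assert {t.nominal_complexity for t in nc} == {forced}
        for t in nc:
            for a, b in zip(t.ordered_bits, t.ordered_bits[1:]):
                assert feature_distance(a, b) >= 2


def test_nonchunkable_adjacency_constraint_all_lengths():
    for length in range(2, 9):
        for t in build_structure_library(length, "nonchunkable"):
            for a, b in zip(t.ordered_bits, t.ordered_bits[1:]):
                assert feature_distance(a, b) >= 2


def test_library_rejects_bad_length():
    with pytest.raises(ValueError):
        build_structure_library(9, "chunkable")
    with pytest.raises(ValueError):
        build_structure_library(3, "mixed")


def test_possible_object_set_counts_records_both_conventions():
    counts = possible_object_set_counts()
    assert counts["unordered_pairs"] == 784
    assert counts["one_dimension_ordered"] == 1568


# ---------------------------------------------------------------------------
# instantiation
# ---------------------------------------------------------------------------

@settings(derandomize=True, max_examples=40, deadline=None)
@given(seed=st.integers(0, 2**31 - 1),
       length=st.integers(1, 8),
       condition=st.sampled_from(["chunkable", "nonchunkable"]))
def test_instantiation_preserves_structure(seed, length, condition):
    rng = np.random.default_rng(seed)
    lib = build_structure_library(length, condition)
    template = lib[rng.integers(0, len(lib))]
    trial = instantiate(template, sample_assignment(rng), rng)
    space = trial.assignment.space()
    bits = tokens_to_bits(trial.memoranda, space)
    # complexity preserved under the random relabeling
    got = minimal_complexity(CategorySet.from_members(space, bits)).minimal_literals
    assert got == template.nominal_complexity
    # pairwise distances preserved
    for (a0, b0), (a1, b1) in zip(
        zip(template.ordered_bits, template.ordered_bits[1:]), zip(bits, bits[1:])
    ):
        assert feature_distance(a0, b0) == feature_distance(a1, b1)


def test_response_screen_is_memoranda_plus_complement_lures():
    rng = np.random.default_rng(0)
    template = build_structure_library(4, "chunkable")[0]
    trial = instantiate(template, sample_assignment(rng), rng)
    assert len(trial.response_screen) == 8
    assert sorted(trial.response_screen) == sorted(trial.memoranda + trial.lures)
    space = trial.assignment.space()
    mem = CategorySet.from_members(space, tokens_to_bits(trial.memoranda, space))
    lure = CategorySet.from_members(space, tokens_to_bits(trial.lures, space))
    assert lure.members == complement(mem).members
    # parity: the lure set is exactly as complex as the memoranda
    assert (
        minimal_complexity(lure).minimal_literals
        == minimal_complexity(mem).minimal_literals
    )


# ---------------------------------------------------------------------------
# block schedule
# ---------------------------------------------------------------------------

def test_block_schedule_shape():
    rng = np.random.default_rng(3)
    block = build_block("chunkable", "simple", rng)
    assert len(block) == 35  # 3 practice + 8 lengths x 4 trials
    practice = [t for t in block if t.is_practice]
    assert [t.length for t in practice] == [1, 1, 2]
    scored = [t for t in block if not t.is_practice]
    assert [t.length for t in scored] == [L for L in range(1, 9) for _ in range(4)]


def test_nonchunkable_block_alternates_most_and_less_incompressible():
    rng = np.random.default_rng(4)
    block = build_block("nonchunkable", "complex", rng)
    scored = [t for t in block if not t.is_practice]
    for i, trial in enumerate(scored):
        expected = "most" if i % 4 in (0, 2) else "less"
        assert trial.template.incompressibility_rank == expected


def test_consecutive_trials_never_share_an_assignment():
    rng = np.random.default_rng(5)
    block = build_block("chunkable", "simple", rng)
    for a, b in zip(block, block[1:]):
        assert a.assignment != b.assignment
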