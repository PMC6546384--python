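"""Parsimony lengths and ACCTRAN/DELTRAN resolutions against brute force."""


import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from homoplasy import parsimony as P
from homoplasy.core import MISSING, Phylogeny

from conftest import brute_force_mprs, change_depth_sum, column_for, random_topology


@pytest.mark.parametrize(
    "states, expected_m, expected_g",
    [
        ([0, 1, 1, 0], 1, 2),
        ([0, 1, 2, MISSING], 2, 2),
        ([0, 0, 0, 0], 0, 0),
        ([0, 1, 2, 2, 2], 2, 2),
    ],
)
def test_step_bounds(states, expected_m, expected_g):
    """m = distinct observed states - 1; g = observed leaves - largest class."""
    col = np.array(states)
    assert P.min_steps(col) == expected_m
    assert P.max_steps(col) == expected_g


def test_step_bounds_reject_all_missing():
    with pytest.raises(ValueError):
        P.min_steps(np.array([MISSING, MISSING]))
    with pytest.raises(ValueError):
        P.max_steps(np.array([MISSING]))


@pytest.mark.parametrize(
    "mapping, expected",
    [
        ({"A": 0, "B": 1, "C": 0, "D": 1}, 2),  # derived twice whichever root
        ({"A": 1, "B": 1, "C": 0, "D": 0}, 1),  # perfect synapomorphy
        ({"A": 0, "B": 0, "C": 0, "D": 0}, 0),  # invariant
        ({"A": 0, "B": 1, "C": 2, "D": MISSING}, 2),
    ],
)
def test_quartet_lengths(quartet, mapping, expected):
    assert P.parsimony_length(quartet, column_for(quartet, mapping)) == expected


def test_star_tree_length():
    """On a star tree the length is n_observed minus the largest state class."""
    star = Phylogeny([[], [], [], [], [0, 1, 2, 3]], {0: "A", 1: "B", 2: "C", 3: "D"})
    col = np.array([0, 0, 1, 2])
    assert P.parsimony_length(star, col) == 2


def test_exhaustive_small_trees_match_brute_force():
    """DP length and both resolutions agree with full MPR enumeration.

    Random rooted topologies (with polytomies) up to 8 taxa, up to 4 states,
    with occasional missing leaves; the oracle enumerates every assignment.
    """
    rng = np.random.default_rng(20240601)
    for _ in range(120):
        n = int(rng.integers(3, 9))
        labels = [f"L{i}" for i in range(n)]
        tree = random_topology(labels, rng)
        k = int(rng.integers(2, 5))
        col = rng.integers(0, k, size=n)
        if rng.random() < 0.3:
            col[int(rng.integers(n))] = MISSING
        arr = column_for(tree, dict(zip(labels, col.tolist())))
        if np.all(arr == MISSING):
            continue
        alphabet = sorted(int(x) for x in np.unique(arr[arr != MISSING]))
        leaf_states = {v: int(arr[tree.taxa.index(tree.taxon_of[v])]) for v in tree.leaves}
        best, mprs = brute_force_mprs(tree, leaf_states, alphabet)
        assert P.parsimony_length(tree, arr) == best
        depth_sums = [change_depth_sum(tree, m) for m in mprs]
        for model, target in ((P.ACCTRAN, min(depth_sums)), (P.DELTRAN, max(depth_sums))):
            states, changes = P.resolve_column(tree, arr, model)
            assert len(changes) == best
            got = change_depth_sum(tree, {v: int(s) for v, s in enumerate(states)})
            assert got == target


def test_acctran_deltran_depth_ordering(six_tree):
    """Change depth: ACCTRAN <= DELTRAN; equal lengths; changes are consistent."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        arr = rng.integers(0, 3, size=6)
        sa, ca = P.resolve_column(six_tree, arr, P.ACCTRAN)
        sd, cd = P.resolve_column(six_tree, arr, P.DELTRAN)
        assert len(ca) == len(cd)
        da = change_depth_sum(six_tree, dict(enumerate(sa.tolist())))
        dd = change_depth_sum(six_tree, dict(enumerate(sd.tolist())))
        assert da <= dd
        for states, changes in ((sa, ca), (sd, cd)):
            for (p, c, frm, to) in changes:
                assert states[p] == frm and states[c] == to


def test_deltran_prefers_parallel_terminal_gains(quartet):
    """1/0/1/0 leaves: DELTRAN puts two independent gains on terminal edges."""
    arr = column_for(quartet, {"A": 1, "B": 0, "C": 1, "D": 0})
    states, changes = P.resolve_column(quartet, arr, P.DELTRAN)
    # root and both internal cherries keep state 0; changes on A and C edges
    assert states[quartet.root] == 0
    child_nodes = sorted(c for (_, c, _, _) in changes)
    assert child_nodes == [quartet.leaf_of["A"], quartet.leaf_of["C"]]


def test_invariant_character_resolves_without_changes(quartet):
    arr = column_for(quartet, {"A": 2, "B": 2, "C": 2, "D": 2})
    for model in P.MODELS:
        states, changes = P.resolve_column(quartet, arr, model)
        assert changes == []
        assert set(states.tolist()) == {2}


def test_missing_leaves_never_increase_length(six_tree):
    """Blanking a leaf cannot raise the parsimony length vs pruning it."""
    rng = np.random.default_rng(11)
    labels = six_tree.taxa
    for _ in range(30):
        full = dict(zip(labels, rng.integers(0, 3, size=6).tolist()))
        drop = labels[int(rng.integers(6))]
        with_missing = dict(full)
        with_missing[drop] = MISSING
        if len({v for k, v in full.items() if k != drop}) < 2:
            continue
        pruned = six_tree.prune_taxa([drop])
        s_missing = P.parsimony_length(six_tree, column_for(six_tree, with_missing))
        s_pruned = P.parsimony_length(
            pruned, np.array([full[t] for t in pruned.taxa])
        )
        assert s_missing <= s_pruned + 0  # equal leaf info, ambiguity can only help
        assert s_missing <= P.parsimony_length(six_tree, column_for(six_tree, full))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=st.lists(st.integers(min_value=0, max_value=3), min_size=4, max_size=4)
)
def test_quartet_all_state_patterns_match_oracle(data):
    """Every 4-taxon pattern over 4 states: DP length equals enumeration."""
    quartet = Phylogeny.from_nested((("A", "B"), ("C", "D")))
    arr = column_for(quartet, dict(zip(["A", "B", "C", "D"], data)))
    alphabet = sorted(set(data))
    leaf_states = {quartet.leaf_of[t]: v for t, v in zip(["A", "B", "C", "D"], data)}
    best, _ = brute_force_mprs(quartet, leaf_states, alphabet)
    assert P.parsimony_length(quartet, arr) == best


def test_reconstruct_matrix_consistency(quartet, toy_matrix):
    """Matrix-level driver: s counts, change tables and bulk lengths agree."""
    for model in P.MODELS:
        rec = P.reconstruct(quartet, toy_matrix, model)
        assert rec.s.tolist() == [1, 2, 0]
        assert rec.m.tolist() == [1, 1, 0]
        assert rec.g.tolist() == [2, 2, 0]
        table = rec.change_table()
        assert len(table) == rec.s.sum()
    identity = np.arange(toy_matrix.n_taxa)[None, :]
    assert P.bulk_lengths(quartet, toy_matrix, identity)[0] == 3


def test_bulk_lengths_match_per_character(six_tree):
    """Vectorised Hartigan equals the scalar implementation under shuffles."""
    from homoplasy.core import CharacterMatrix, default_char_meta

    rng = np.random.default_rng(3)
    states = rng.integers(0, 3, size=(6, 25)).astype(np.int16)
    states[rng.random(states.shape) < 0.2] = MISSING
    states[:, 0] = 0  # keep one invariant character in the mix
    matrix = CharacterMatrix(six_tree.taxa, states, default_char_meta(25))
    orders = np.stack([rng.permutation(6) for _ in range(8)])
    bulk = P.bulk_lengths(six_tree, matrix, orders)
    for p in range(8):
        shuffled = CharacterMatrix(
            matrix.taxa, matrix.states[orders[p], :], matrix.char_meta.copy()
        )
        expected = sum(
            P.parsimony_length(six_tree, shuffled.column(j), shuffled.taxa)
            for j in range(25)
        )
        assert bulk[p] == expected
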