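"""Shared fixtures: small hand-built trees, toy matrices, and brute-force
parsimony oracles used to validate the dynamic-programming implementation."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from homoplasy.core import MISSING, CharacterMatrix, Phylogeny, default_char_meta


# ---------------------------------------------------------------------------
# brute-force parsimony oracle (independent of the DP implementation)
# ---------------------------------------------------------------------------

def brute_force_mprs(tree: Phylogeny, leaf_states: dict[int, int], alphabet):
    """Enumerate every ancestral assignment; return (min length, list of MPRs).

    Missing leaves are enumerated over the alphabet like internal nodes.
    Feasible only for small trees.
    """
    internals = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    free = [v for v in tree.leaves if leaf_states.get(v, MISSING) == MISSING]
    slots = internals + free
    best, mprs = None, []
    for combo in itertools.product(alphabet, repeat=len(slots)):
        st = dict(zip(slots, combo))
        for v in tree.leaves:
            if leaf_states.get(v, MISSING) != MISSING:
                st[v] = leaf_states[v]
        length = sum(
            1
            for v in range(tree.n_nodes)
            if v != tree.root and st[v] != st[int(tree.parent[v])]
        )
        if best is None or length < best:
            best, mprs = length, [st]
        elif length == best:
            mprs.append(st)
    return best, mprs


def change_depth_sum(tree: Phylogeny, assignment: dict[int, int]) -> int:
    """Sum of parent depths over change edges (root depth 0)."""
    d = tree.depths()
    return sum(
        int(d[int(tree.parent[v])])
        for v in range(tree.n_nodes)
        if v != tree.root and assignment[v] != assignment[int(tree.parent[v])]
    )


def random_topology(labels, rng) -> Phylogeny:
    """Random rooted topology over the labels, with occasional polytomies."""
    items = list(labels)
    while len(items) > 1:
        k = int(rng.integers(2, min(3, len(items)) + 1))
        picks = [items.pop(int(rng.integers(len(items)))) for _ in range(k)]
        items.append(tuple(picks))
    return Phylogeny.from_nested(items[0])


@pytest.fixture
def oracle():
    return brute_force_mprs


# ---------------------------------------------------------------------------
# small fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def quartet() -> Phylogeny:
    """((A,B),(C,D)) — post-order ids: A=0 B=1 AB=2 C=3 D=4 CD=5 root=6."""
    return Phylogeny.from_nested((("A", "B"), ("C", "D")))


@pytest.fixture
def six_tree() -> Phylogeny:
    """(((A,B),C),((D,E),F)) pectinate-ish six-taxon tree."""
    return Phylogeny.from_nested(((("A", "B"), "C"), (("D", "E"), "F")))


def column_for(tree: Phylogeny, mapping: dict[str, int]) -> np.ndarray:
    return np.array([mapping.get(t, MISSING) for t in tree.taxa], dtype=np.int64)


def matrix_for(tree: Phylogeny, columns: list[dict[str, int]]) -> CharacterMatrix:
    taxa = tree.taxa
    states = np.stack(
        [[m.get(t, MISSING) for m in columns] for t in taxa]
    ).astype(np.int16)
    return CharacterMatrix(taxa, states, default_char_meta(len(columns)))


@pytest.fixture
def toy_matrix(quartet) -> CharacterMatrix:
    """Three characters: clean synapomorphy, homoplastic binary, invariant."""
    return matrix_for(
        quartet,
        [
            {"A": 1, "B": 1, "C": 0, "D": 0},  # synapomorphy, m=s=1
            {"A": 0, "B": 1, "C": 0, "D": 1},  # homoplasy, m=1 s=2 g=2
            {"A": 0, "B": 0, "C": 0, "D": 0},  # invariant
        ],
    )
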