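"""Maximum-parsimony reconstruction of unordered multistate characters.

Tree length is the Fitch/Hartigan minimum on a rooted, possibly polytomous
tree; missing observations act as full ambiguity over the character's observed
alphabet.  Among all most-parsimonious reconstructions (MPRs) two canonical
resolutions are produced:

* ACCTRAN — accelerated transformation: changes are pulled as close to the
  root as possible, favouring reversals;
* DELTRAN — delayed transformation: changes are pushed toward the tips,
  favouring parallel gains.

Both are computed exactly with a lexicographic dynamic programme whose primary
objective is the change count and whose secondary objective is the summed
topological depth of change edges (minimised for ACCTRAN, maximised for
DELTRAN); remaining ties break toward the smallest state code, so results are
deterministic.  Internal nodes are restricted to each character's observed
alphabet — with unit change costs an unobserved intermediate can never shorten
a reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, CharacterMatrix, Phylogeny

ACCTRAN = "ACCTRAN"
DELTRAN = "DELTRAN"
MODELS = (ACCTRAN, DELTRAN)

_INF = 10**9


# ---------------------------------------------------------------------------
# step-count bounds
# ---------------------------------------------------------------------------

def min_steps(column: np.ndarray) -> int:
    """Minimum conceivable steps m: distinct observed states minus one."""
    obs = column[np.asarray(column) != MISSING]
    if obs.size == 0:
        raise ValueError("character has no observed states")
    return int(np.unique(obs).size - 1)


def max_steps(column: np.ndarray) -> int:
    """Maximum steps g on a star tree: observed leaves minus the largest state class."""
    obs = np.asarray(column)[np.asarray(column) != MISSING]
    if obs.size == 0:
        raise ValueError("character has no observed states")
    _, counts = np.unique(obs, return_counts=True)
    return int(obs.size - counts.max())


# ---------------------------------------------------------------------------
# Hartigan length
# ---------------------------------------------------------------------------

def parsimony_length(tree: Phylogeny, column: np.ndarray, taxa: list[str] | None = None) -> int:
    """Minimum number of state changes for one character on a rooted tree.

    ``column`` holds one state (or MISSING) per taxon, ordered as ``taxa``
    (defaults to the tree's own leaf order).
    """
    states = _leaf_states(tree, column, taxa)
    alphabet = np.unique(states[states != MISSING])
    if alphabet.size == 0:
        raise ValueError("character has no observed states")
    amap = {int(s): i for i, s in enumerate(alphabet)}
    k = alphabet.size
    full = (1 << k) - 1
    mask = np.zeros(tree.n_nodes, dtype=np.int64)
    length = 0
    for v in tree.postorder():
        if tree.is_leaf(v):
            s = states[v]
            mask[v] = full if s == MISSING else (1 << amap[int(s)])
        else:
            counts = [0] * k
            for c in tree.children[v]:
                m = mask[c]
                for i in range(k):
                    if m >> i & 1:
                        counts[i] += 1
            best = max(counts)
            length += len(tree.children[v]) - best
            mask[v] = sum(1 << i for i in range(k) if counts[i] == best)
    return length


def _leaf_states(tree: Phylogeny, column, taxa) -> np.ndarray:
    column = np.asarray(column)
    out = np.full(tree.n_nodes, MISSING, dtype=np.int64)
    if taxa is None:
        taxa = tree.taxa
    if len(taxa) != column.size:
        raise ValueError("column length does not match taxa")
    for t, s in zip(taxa, column):
        if t not in tree.leaf_of:
            raise ValueError(f"taxon '{t}' not on tree")
        out[tree.leaf_of[t]] = s
    for v in tree.leaves:
        if tree.taxon_of[v] not in set(taxa):
            raise ValueError(f"leaf '{tree.taxon_of[v]}' has no state mapping")
    return out


# ---------------------------------------------------------------------------
# resolved reconstructions
# ---------------------------------------------------------------------------

@dataclass
class Reconstruction:
    """Per-character ancestral states and change lists under one resolution."""

    model: str
    tree: Phylogeny
    matrix: CharacterMatrix
    node_states: np.ndarray  # (n_chars, n_nodes) int16
    changes: list[list[tuple[int, int, int, int]]]  # per char: (parent, child, from, to)
    m: np.ndarray
    s: np.ndarray
    g: np.ndarray

    @property
    def n_chars(self) -> int:
        return self.node_states.shape[0]

    def root_state(self, j: int) -> int:
        return int(self.node_states[j, self.tree.root])

    def change_table(self) -> pd.DataFrame:
        """One row per state change: char_id, parent/child node, from/to, model."""
        rows = []
        ids = list(self.matrix.char_meta["id"])
        for j, chs in enumerate(self.changes):
            for (p, c, a, b) in chs:
                rows.append(
                    {
                        "char_id": ids[j],
                        "parent_node": p,
                        "child_node": c,
                        "from_state": a,
                        "to_state": b,
                        "model": self.model,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["char_id", "parent_node", "child_node", "from_state", "to_state", "model"],
        )

    def node_state_table(self) -> pd.DataFrame:
        ids = list(self.matrix.char_meta["id"])
        df = pd.DataFrame(self.node_states.T, columns=ids)
        df.insert(0, "node", np.arange(self.tree.n_nodes))
        df.insert(1, "is_leaf", [self.tree.is_leaf(v) for v in range(self.tree.n_nodes)])
        return df


def resolve_column(
    tree: Phylogeny, column: np.ndarray, model: str, taxa: list[str] | None = None
) -> tuple[np.ndarray, list[tuple[int, int, int, int]]]:
    """Single most-parsimonious node-state assignment for one character.

    Returns the per-node state vector and the change list (parent, child,
    from_state, to_state); ``len(changes)`` equals the Hartigan minimum.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    leaf_states = _leaf_states(tree, column, taxa)
    alphabet = [int(s) for s in np.unique(leaf_states[leaf_states != MISSING])]
    if not alphabet:
        raise ValueError("character has no observed states")
    k = len(alphabet)
    idx = {s: i for i, s in enumerate(alphabet)}
    depth = tree.depths()
    # secondary objective weight: +depth for ACCTRAN (minimise), -depth for DELTRAN
    sign = 1 if model == ACCTRAN else -1

    P = np.zeros((tree.n_nodes, k), dtype=np.int64)
    S = np.zeros((tree.n_nodes, k), dtype=np.int64)
    for v in tree.postorder():
        if tree.is_leaf(v):
            s = leaf_states[v]
            if s != MISSING:
                P[v, :] = _INF
                P[v, idx[int(s)]] = 0
        else:
            sec = sign * int(depth[v])  # depth of edge v->child = depth(v)
            for c in tree.children[v]:
                Pc, Sc = P[c], S[c]
                for a in range(k):
                    bp, bs = Pc[a], Sc[a]  # stay
                    for b in range(k):
                        if b == a:
                            continue
                        cp, cs = Pc[b] + 1, Sc[b] + sec
                        if cp < bp or (cp == bp and cs < bs):
                            bp, bs = cp, cs
                    P[v, a] += bp
                    S[v, a] += bs

    # choose root state: lexicographic (P, S), ties -> smallest state code
    root = tree.root
    best = 0
    for a in range(1, k):
        if (P[root, a], S[root, a]) < (P[root, best], S[root, best]):
            best = a
    assign = np.full(tree.n_nodes, -1, dtype=np.int64)
    assign[root] = best
    changes: list[tuple[int, int, int, int]] = []
    for v in tree.parents_first():
        if tree.is_leaf(v):
            continue
        a = assign[v]
        sec = sign * int(depth[v])
        for c in tree.children[v]:
            bb, bp, bs = None, None, None
            for b in range(k):
                cp = P[c, b] + (1 if b != a else 0)
                cs = S[c, b] + (sec if b != a else 0)
                if bb is None or (cp, cs) < (bp, bs):
                    bb, bp, bs = b, cp, cs
            assign[c] = bb
            if bb != a:
                changes.append((int(v), int(c), alphabet[a], alphabet[bb]))
    states = np.array([alphabet[a] for a in assign], dtype=np.int16)
    return states, changes


def reconstruct(tree: Phylogeny, matrix: CharacterMatrix, model: str) -> Reconstruction:
    """Resolve every character of the matrix on one rooted tree."""
    n_chars = matrix.n_chars
    node_states = np.zeros((n_chars, tree.n_nodes), dtype=np.int16)
    changes: list[list[tuple[int, int, int, int]]] = []
    m = np.zeros(n_chars, dtype=np.int64)
    s = np.zeros(n_chars, dtype=np.int64)
    g = np.zeros(n_chars, dtype=np.int64)
    for j in range(n_chars):
        col = matrix.column(j)
        st, chs = resolve_column(tree, col, model, matrix.taxa)
        node_states[j] = st
        changes.append(chs)
        m[j] = min_steps(col)
        s[j] = len(chs)
        g[j] = max_steps(col)
    rec = Reconstruction(model, tree, matrix, node_states, changes, m, s, g)
    if np.any(rec.s < rec.m):
        raise AssertionError("observed steps fell below the minimum — internal error")
    return rec


def parsimony_lengths(tree: Phylogeny, matrix: CharacterMatrix) -> np.ndarray:
    """Hartigan length of every character (no resolution)."""
    return np.array(
        [parsimony_length(tree, matrix.column(j), matrix.taxa) for j in range(matrix.n_chars)],
        dtype=np.int64,
    )


# ---------------------------------------------------------------------------
# vectorised bulk lengths (used by the permutation null)
# ---------------------------------------------------------------------------

def bulk_lengths(tree: Phylogeny, matrix: CharacterMatrix, row_orders: np.ndarray) -> np.ndarray:
    """Hartigan lengths of all characters under many taxon permutations.

    ``row_orders`` is (n_perm, n_taxa): replicate p assigns matrix row
    ``row_orders[p, i]`` to the taxon at matrix position ``i``.  Returns the
    per-replicate total step count, summed over characters (the per-character
    minima m and maxima g are invariant under taxon permutation).
    """
    row_orders = np.asarray(row_orders)
    n_perm, n_taxa = row_orders.shape
    if n_taxa != matrix.n_taxa:
        raise ValueError("row_orders width does not match matrix taxa")
    n_chars = matrix.n_chars
    # per-character alphabet -> bit positions
    tipcode = np.zeros((n_taxa, n_chars), dtype=np.uint16)
    kmax = 1
    for j in range(n_chars):
        alphabet = matrix.alphabet(j)
        k = alphabet.size
        kmax = max(kmax, k)
        col = matrix.column(j)
        code = np.zeros(n_taxa, dtype=np.uint16)
        full = (1 << k) - 1
        for i, s in enumerate(col):
            code[i] = full if s == MISSING else (1 << int(np.searchsorted(alphabet, s)))
        tipcode[:, j] = code

    pos_of_taxon = {t: i for i, t in enumerate(matrix.taxa)}
    total = np.zeros(n_perm, dtype=np.int64)
    masks: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            i = pos_of_taxon[tree.taxon_of[v]]
            masks[v] = tipcode[row_orders[:, i], :]  # (n_perm, n_chars)
        else:
            kids = tree.children[v]
            counts = np.zeros((kmax, n_perm, n_chars), dtype=np.uint8)
            for c in kids:
                mc = masks.pop(c)
                for b in range(kmax):
                    counts[b] += (mc >> b) & 1
            best = counts.max(axis=0)
            total += (len(kids) - best.astype(np.int64)).sum(axis=1)
            mv = np.zeros((n_perm, n_chars), dtype=np.uint16)
            for b in range(kmax):
                mv |= (counts[b] == best).astype(np.uint16) << b
            masks[v] = mv
    return total
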