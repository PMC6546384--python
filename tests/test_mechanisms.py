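"""Pairwise mechanism classification, reversal counting, and the
combinatorial-counting vs explicit-pair-loop cross-check."""

import itertools

import numpy as np
import pytest

from homoplasy import mechanisms as M
from homoplasy import parsimony as P
from homoplasy.core import MISSING, Phylogeny
from homoplasy.synthetic_data import SimulationConfig, simulate_dataset

from conftest import matrix_for


def records_for(tree, columns, model=P.ACCTRAN):
    rec = P.reconstruct(tree, matrix_for(tree, columns), model)
    return rec, M.derivation_records(rec)


def pair_dicts(records, char_index=0):
    """Per-taxon record dicts for one character, in taxon order."""
    table = records.to_table()
    cid = records.char_ids[char_index]
    return [row for _, row in table[table.char_id == cid].iterrows()]


def explicit_counts(records):
    """Independent route: classify every valid pair with classify_pair."""
    out = {}
    table = records.to_table()
    for cid, grp in table.groupby("char_id", sort=False):
        counts = dict.fromkeys(M.MECHANISMS, 0)
        rows = [r for _, r in grp.iterrows()]
        for a, b in itertools.combinations(rows, 2):
            counts[M.classify_pair(a, b)] += 1
        out[cid] = counts
    return out


# ---------------------------------------------------------------------------
# classify_pair on constructed fixtures
# ---------------------------------------------------------------------------

def test_inertia_shared_synapomorphy(quartet):
    """A and B share state 1 gained once on their stem: inertia."""
    _, recs = records_for(quartet, [{"A": 1, "B": 1, "C": 0, "D": 0}])
    a, b, c, d = pair_dicts(recs)
    assert M.classify_pair(a, b) == "inertia"
    assert M.classify_pair(c, d) == "inertia"  # both untouched root state


def test_parallelism_independent_gains_same_origin(quartet):
    """1/0/1/0 under DELTRAN: A and C gained 1 independently from the same
    ancestral 0 — parallelism; B and D keep 0 of one origin — inertia."""
    _, recs = records_for(quartet, [{"A": 1, "B": 0, "C": 1, "D": 0}], P.DELTRAN)
    a, b, c, d = pair_dicts(recs)
    assert M.classify_pair(a, c) == "parallelism"
    assert M.classify_pair(b, d) == "inertia"


def test_convergence_same_state_different_originals(six_tree):
    """Tips reach state 2 from different predecessor states: convergence.

    (((A,B),C),((D,E),F)) with A=2 via 0->2 and D=2 via 1->2 (DELTRAN keeps
    both changes terminal once 1 is fixed for the right-hand clade)."""
    _, recs = records_for(
        six_tree,
        [{"A": 2, "B": 0, "C": 0, "D": 2, "E": 1, "F": 1}],
        P.DELTRAN,
    )
    table = recs.to_table().set_index("taxon")
    a, d = table.loc["A"], table.loc["D"]
    assert a.current == d.current == 2
    if a.original != d.original:
        assert M.classify_pair(a, d) == "convergence"
    else:  # resolution happened to equalise originals: then parallelism
        assert M.classify_pair(a, d) == "parallelism"


def test_divergence_requires_co_departure(quartet):
    """Under DELTRAN, A=1 (gain on its own edge) vs B=0 (unchanged) is not
    divergence: B never changed (depart_node -1)."""
    _, recs = records_for(quartet, [{"A": 1, "B": 0, "C": 0, "D": 0}], P.DELTRAN)
    a, b, _, _ = pair_dicts(recs)
    assert a.current != b.current
    assert M.classify_pair(a, b) != "divergence"


def test_divergence_sister_departures():
    """Hand-built records: two changes leaving the same node with equal
    originals but different outcomes classify as divergence."""
    a = {"char_id": "c", "current": 1, "original": 0, "change_node": 4,
         "origin_node": 6, "depart_node": 5}
    b = {"char_id": "c", "current": 2, "original": 0, "change_node": 3,
         "origin_node": 6, "depart_node": 5}
    assert M.classify_pair(a, b) == "divergence"
    # different departure nodes, independent origins -> disparity1
    b2 = dict(b, depart_node=2, origin_node=1)
    assert M.classify_pair(a, b2) == "disparity1"
    # different original states -> disparity2
    b3 = dict(b, original=1)
    assert M.classify_pair(a, b3) == "disparity2"


def test_classify_pair_symmetry(six_tree):
    rng = np.random.default_rng(31)
    cols = [dict(zip(six_tree.taxa, rng.integers(0, 3, size=6).tolist())) for _ in range(10)]
    for model in P.MODELS:
        _, recs = records_for(six_tree, cols, model)
        table = recs.to_table()
        for cid, grp in table.groupby("char_id", sort=False):
            rows = [r for _, r in grp.iterrows()]
            for a, b in itertools.combinations(rows, 2):
                assert M.classify_pair(a, b) == M.classify_pair(b, a)


def test_classify_pair_rejects_cross_character():
    a = {"char_id": "c1", "current": 0, "original": 0, "change_node": 0,
         "origin_node": 0, "depart_node": -1}
    b = dict(a, char_id="c2")
    with pytest.raises(ValueError):
        M.classify_pair(a, b)


# ---------------------------------------------------------------------------
# combinatorial counting vs the explicit pair loop
# ---------------------------------------------------------------------------

def test_counts_match_explicit_pair_loop():
    """The O(n) group-counting route equals classifying all pairs, including
    with missing data, on both resolutions."""
    tree, matrix, _ = simulate_dataset(SimulationConfig(seed=21).scaled(35))
    for model in P.MODELS:
        rec = P.reconstruct(tree, matrix, model)
        recs = M.derivation_records(rec)
        fast = M.mechanism_counts_per_char(recs).set_index("char_id")
        slow = explicit_counts(recs)
        for cid, counts in slow.items():
            for mech in M.MECHANISMS:
                assert fast.loc[cid, mech] == counts[mech], (model, cid, mech)


def test_proportions_sum_to_one(six_tree):
    rng = np.random.default_rng(5)
    cols = [dict(zip(six_tree.taxa, rng.integers(0, 4, size=6).tolist())) for _ in range(20)]
    for model in P.MODELS:
        _, recs = records_for(six_tree, cols, model)
        for mode in ("pooled", "per_char_mean"):
            out = M.mechanism_proportions(recs, mode)
            assert sum(out["proportions"].values()) == pytest.approx(1.0)
            assert 0.0 <= out["similar_state_homoplasy_share"] <= 1.0


def test_missing_tips_excluded_from_pairs(quartet):
    """A missing observation removes the taxon from that character's pairs."""
    _, recs = records_for(quartet, [{"A": 1, "B": 1, "C": 0, "D": MISSING}])
    counts = M.mechanism_counts_per_char(recs)
    assert counts.n_pairs.iloc[0] == 3  # C(3,2)


def test_acctran_divergence_rare():
    """Accelerated transformation pulls sister departures apart: divergence
    is (near) absent under ACCTRAN and rare under DELTRAN."""
    tree, matrix, _ = simulate_dataset(SimulationConfig(seed=2).scaled(10))
    rec_a = P.reconstruct(tree, matrix, P.ACCTRAN)
    rec_d = P.reconstruct(tree, matrix, P.DELTRAN)
    prop_a = M.mechanism_proportions(M.derivation_records(rec_a))["proportions"]
    prop_d = M.mechanism_proportions(M.derivation_records(rec_d))["proportions"]
    assert prop_a["divergence"] <= 0.001
    assert prop_d["divergence"] <= 0.02


# ---------------------------------------------------------------------------
# reversals
# ---------------------------------------------------------------------------

def test_reversal_single_incidence(six_tree):
    """Comparison count equals the sum of root-path lengths over observed
    tips, and any_reversal tracks the incidence count."""
    col = {"A": 1, "B": 1, "C": 1, "D": 0, "E": 1, "F": 1}
    rec = P.reconstruct(six_tree, matrix_for(six_tree, [col]), P.ACCTRAN)
    rev = M.count_reversals(rec)
    assert rev.comparisons.iloc[0] == 3 + 3 + 2 + 3 + 3 + 2
    if rec.root_state(0) == 0:
        # 1 fixed deep, D reverted: D's deeper-0 comparisons are incidences
        assert rev.incidences.iloc[0] >= 1
    assert bool(rev.any_reversal.iloc[0]) == (rev.incidences.iloc[0] > 0)


def test_reversal_explicit_path(quartet):
    """Count incidences along a known 0 -> 1 -> 0 root-to-tip path by
    replaying the definition directly on the resolved node states."""
    tree = Phylogeny.from_nested(((("A", "B"), "C"), ("D", "E")))
    col = {"A": 0, "B": 1, "C": 1, "D": 0, "E": 0}
    rec = P.reconstruct(tree, matrix_for(tree, [col]), P.ACCTRAN)
    if rec.root_state(0) == 0 and rec.s[0] == 2:
        states = rec.node_states[0]
        # if the (A,B),C ancestor carries 1 while A reverted to 0, A vs root
        # (and A vs any deeper 0 node) is an incidence
        rev = M.count_reversals(rec)
        a_node = tree.leaf_of["A"]
        path = tree.path_to_root(a_node)[1:]
        expected = 0
        seen_diff = False
        for u in path:
            if states[u] != 0:
                seen_diff = True
            elif seen_diff:
                expected += 1
        assert rev.incidences.iloc[0] >= expected


def test_acctran_reversals_geq_deltran():
    """ACCTRAN prefers early gains plus reversals, DELTRAN parallel gains, so
    total reversal incidences satisfy ACCTRAN >= DELTRAN."""
    tree, matrix, _ = simulate_dataset(SimulationConfig(seed=9).scaled(10))
    totals = {}
    for model in P.MODELS:
        rec = P.reconstruct(tree, matrix, model)
        totals[model] = int(M.count_reversals(rec).incidences.sum())
    assert totals[P.ACCTRAN] >= totals[P.DELTRAN]


def test_reversal_mechanism_correlation_bounds():
    tree, matrix, _ = simulate_dataset(SimulationConfig(seed=4).scaled(10))
    rec = P.reconstruct(tree, matrix, P.ACCTRAN)
    rev = M.count_reversals(rec)
    per_char = M.mechanism_counts_per_char(M.derivation_records(rec))
    out = M.reversal_mechanism_correlation(rev, per_char)
    assert 0.0 <= out["r2_convergence"] <= 1.0
    assert 0.0 <= out["r2_parallelism"] <= 1.0


def test_reversal_mechanism_correlation_perfect_line():
    """Hand-built collinear data gives R^2 = 1 for convergence."""
    import pandas as pd

    rev = pd.DataFrame(
        {"char_id": list("abcd"), "incidences": [0, 1, 2, 3],
         "comparisons": [10] * 4, "fraction": [0.0, 0.1, 0.2, 0.3],
         "any_reversal": [False, True, True, True]}
    )
    mech = pd.DataFrame(
        {"char_id": list("abcd"), "n_pairs": [10] * 4,
         "inertia": [10, 8, 6, 4], "parallelism": [0, 0, 0, 0],
         "convergence": [0, 2, 4, 6], "divergence": [0] * 4,
         "disparity1": [0] * 4, "disparity2": [0] * 4}
    )
    out = M.reversal_mechanism_correlation(rev, mech)
    assert out["r2_convergence"] == pytest.approx(1.0)
    assert out["r2_parallelism"] == 0.0
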