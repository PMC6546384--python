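"""Pairwise mechanisms of resemblance and difference between species.

For every (taxon, character) with an observed state, a derivation record holds
the tip's current state, the state it most recently changed from (its
*original* state), the node where that change happened, and the node where the
original state itself arose.  Each unordered species pair then falls into one
of six categories:

equal current states
    * inertia — the shared state arose once (same change node);
    * parallelism — independent derivations from equal original states;
    * convergence — independent derivations from different original states.

different current states
    * divergence — the two states departed from the same ancestral state at
      the same node (both records changed, equal originals, and their change
      edges leave the same parent node);
    * disparity1 — original states equal in value but of independent origin
      (different origin nodes);
    * disparity2 — everything else: different original states, or originals
      of common origin whose changes did not co-depart.

Divergence is deliberately strict: on a single resolved reconstruction two
lineages can only be said to *diverge* when their different states split off
the very same ancestral node.  Accelerated transformation removes such
configurations (one of the two changes is pulled above the shared node), so
divergence is essentially absent under ACCTRAN and rare under DELTRAN,
whereas a looser "same original state of common origin" reading would absorb
roughly a third of all different-state pairs.

Reversal incidences compare each tip with each of its ancestors: the pair
(ancestor, tip) is a reversal when they share a state while some node strictly
between them shows a different one (e.g. 0 -> 1 -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING
from .parsimony import Reconstruction

MECHANISMS = ("inertia", "parallelism", "convergence", "divergence", "disparity1", "disparity2")


# ---------------------------------------------------------------------------
# derivation records
# ---------------------------------------------------------------------------

@dataclass
class DerivationRecords:
    """Per (character, taxon) arrays; entries for missing observations are -1."""

    taxa: list[str]
    char_ids: list[str]
    current: np.ndarray      # (n_chars, n_taxa) tip state
    original: np.ndarray     # state immediately preceding the last change
    change_node: np.ndarray  # node of the last change (root if none)
    origin_node: np.ndarray  # node where the original state itself arose
    depart_node: np.ndarray  # parent of change_node (-1 if never changed)
    valid: np.ndarray        # bool: tip state observed

    def to_table(self) -> pd.DataFrame:
        rows = []
        for j, cid in enumerate(self.char_ids):
            for i, tax in enumerate(self.taxa):
                if not self.valid[j, i]:
                    continue
                rows.append(
                    {
                        "char_id": cid,
                        "taxon": tax,
                        "current": int(self.current[j, i]),
                        "original": int(self.original[j, i]),
                        "change_node": int(self.change_node[j, i]),
                        "origin_node": int(self.origin_node[j, i]),
                        "depart_node": int(self.depart_node[j, i]),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "char_id", "taxon", "current", "original",
                "change_node", "origin_node", "depart_node",
            ],
        )


def derivation_records(rec: Reconstruction) -> DerivationRecords:
    """Build derivation records by propagating change history from the root.

    On the root-to-tip path the triple (change node, original state, origin of
    the original) updates only at nodes whose resolved state differs from the
    parent's; the tip inherits the triple in force at its position.
    """
    tree, matrix = rec.tree, rec.matrix
    n_chars, n_taxa = rec.n_chars, matrix.n_taxa
    current = np.full((n_chars, n_taxa), -1, dtype=np.int64)
    original = np.full((n_chars, n_taxa), -1, dtype=np.int64)
    change_node = np.full((n_chars, n_taxa), -1, dtype=np.int64)
    origin_node = np.full((n_chars, n_taxa), -1, dtype=np.int64)
    depart_node = np.full((n_chars, n_taxa), -1, dtype=np.int64)
    valid = matrix.states.T != MISSING  # (n_chars, n_taxa)

    leaf_pos = {tree.leaf_of[t]: i for i, t in enumerate(matrix.taxa)}
    for j in range(n_chars):
        st = rec.node_states[j]
        chg = np.empty(tree.n_nodes, dtype=np.int64)
        orig = np.empty(tree.n_nodes, dtype=np.int64)
        origin = np.empty(tree.n_nodes, dtype=np.int64)
        dep = np.empty(tree.n_nodes, dtype=np.int64)
        r = tree.root
        chg[r], orig[r], origin[r], dep[r] = r, st[r], r, -1
        for v in tree.parents_first():
            for c in tree.children[v]:
                if st[c] == st[v]:
                    chg[c], orig[c], origin[c], dep[c] = chg[v], orig[v], origin[v], dep[v]
                else:
                    # a change happened on edge v->c: the new state arose at c,
                    # from v's state, which itself arose at v's own change node
                    chg[c], orig[c], origin[c], dep[c] = c, st[v], chg[v], v
        for v, i in leaf_pos.items():
            current[j, i] = st[v]
            original[j, i] = orig[v]
            change_node[j, i] = chg[v]
            origin_node[j, i] = origin[v]
            depart_node[j, i] = dep[v]
    return DerivationRecords(
        list(matrix.taxa), list(matrix.char_meta["id"]),
        current, original, change_node, origin_node, depart_node, valid,
    )


def classify_pair(rec_a: dict, rec_b: dict) -> str:
    """Classify one unordered pair of derivation records (same character).

    Records are mappings with keys ``current``, ``original``, ``change_node``,
    ``origin_node``, ``depart_node`` (as produced by
    :meth:`DerivationRecords.to_table`).
    """
    if rec_a.get("char_id", None) != rec_b.get("char_id", None):
        raise ValueError("records belong to different characters")
    if rec_a["current"] == rec_b["current"]:
        if rec_a["change_node"] == rec_b["change_node"]:
            return "inertia"
        if rec_a["original"] == rec_b["original"]:
            return "parallelism"
        return "convergence"
    if rec_a["original"] == rec_b["original"]:
        if rec_a["depart_node"] == rec_b["depart_node"] and rec_a["depart_node"] != -1:
            return "divergence"
        if rec_a["origin_node"] != rec_b["origin_node"]:
            return "disparity1"
    return "disparity2"


# ---------------------------------------------------------------------------
# mechanism proportions
# ---------------------------------------------------------------------------

def _pairs(counts: np.ndarray) -> np.ndarray:
    return counts * (counts - 1) // 2


def mechanism_counts_per_char(records: DerivationRecords) -> pd.DataFrame:
    """Counts of the six categories per character over all valid pairs.

    Uses combinatorial group counting (sums of C(n,2) over signature groups),
    equivalent to classifying every pair explicitly.
    """
    rows = []
    for j, cid in enumerate(records.char_ids):
        ok = records.valid[j]
        cur = records.current[j, ok]
        orig = records.original[j, ok]
        chg = records.change_node[j, ok]
        origin = records.origin_node[j, ok]
        depart = records.depart_node[j, ok]
        n = cur.size
        total = n * (n - 1) // 2
        changed = depart >= 0

        def group_pairs(*keys, mask=None) -> int:
            if n == 0:
                return 0
            sig = np.stack(keys, axis=1)
            if mask is not None:
                sig = sig[mask]
            if len(sig) == 0:
                return 0
            _, cnt = np.unique(sig, axis=0, return_counts=True)
            return int(_pairs(cnt).sum())

        same_cur = group_pairs(cur)
        inertia = group_pairs(cur, chg)
        same_cur_orig = group_pairs(cur, orig)
        parallelism = same_cur_orig - inertia
        convergence = same_cur - same_cur_orig

        # different-current branch
        diff_cur = total - same_cur
        # divergence: both changed, equal originals, changes leave the same node
        divergence = group_pairs(orig, depart, mask=changed) - group_pairs(
            orig, depart, cur, mask=changed
        )
        # disparity1: equal original values of independent origin
        same_orig_diffcur = group_pairs(orig) - group_pairs(orig, cur)
        same_orig_origin_diffcur = group_pairs(orig, origin) - group_pairs(orig, origin, cur)
        disparity1 = same_orig_diffcur - same_orig_origin_diffcur
        disparity2 = diff_cur - divergence - disparity1

        rows.append(
            {
                "char_id": cid,
                "n_pairs": total,
                "inertia": inertia,
                "parallelism": parallelism,
                "convergence": convergence,
                "divergence": divergence,
                "disparity1": disparity1,
                "disparity2": disparity2,
            }
        )
    return pd.DataFrame(rows, columns=["char_id", "n_pairs", *MECHANISMS])


def mechanism_proportions(records: DerivationRecords, mode: str = "pooled") -> dict:
    """Proportions of the six categories, pooled or averaged per character.

    Also reports the similarity-conditional homoplasy share
    (parallelism + convergence) / (inertia + parallelism + convergence).
    """
    per_char = mechanism_counts_per_char(records)
    usable = per_char[per_char["n_pairs"] > 0]
    if usable.empty:
        raise ValueError("no valid pairs in any character")
    if mode == "pooled":
        totals = usable[list(MECHANISMS)].sum()
        n_pairs = int(usable["n_pairs"].sum())
        props = {m: float(totals[m]) / n_pairs for m in MECHANISMS}
    elif mode == "per_char_mean":
        frac = usable[list(MECHANISMS)].div(usable["n_pairs"], axis=0)
        n_pairs = int(usable["n_pairs"].sum())
        props = {m: float(frac[m].mean()) for m in MECHANISMS}
    else:
        raise ValueError("mode must be 'pooled' or 'per_char_mean'")
    totals = usable[list(MECHANISMS)].sum()
    similar = float(totals["inertia"] + totals["parallelism"] + totals["convergence"])
    homopl = float(totals["parallelism"] + totals["convergence"])
    return {
        "mode": mode,
        "n_pairs": n_pairs,
        "proportions": props,
        "counts": {m: int(totals[m]) for m in MECHANISMS},
        "similar_state_homoplasy_share": homopl / similar if similar else float("nan"),
        "per_char": per_char,
    }


# ---------------------------------------------------------------------------
# reversals
# ---------------------------------------------------------------------------

def count_reversals(rec: Reconstruction) -> pd.DataFrame:
    """Per-character reversal incidences among (taxon, ancestor) comparisons.

    For each observed tip and each of its strict ancestors, a comparison is a
    reversal incidence when the two share a state while some node strictly
    between them differs.  The per-character fraction divides incidences by
    all comparisons; ``any_reversal`` flags characters with at least one.
    """
    tree, matrix = rec.tree, rec.matrix
    rows = []
    tip_nodes = [(tree.leaf_of[t], i) for i, t in enumerate(matrix.taxa)]
    for j, cid in enumerate(matrix.char_meta["id"]):
        st = rec.node_states[j]
        incid = 0
        comp = 0
        for v, i in tip_nodes:
            if matrix.states[i, j] == MISSING:
                continue
            tip_state = st[v]
            seen_diff = False
            u = v
            while u != tree.root:
                u = int(tree.parent[u])
                comp += 1
                if st[u] != tip_state:
                    seen_diff = True
                elif seen_diff:
                    incid += 1
        rows.append(
            {
                "char_id": cid,
                "incidences": incid,
                "comparisons": comp,
                "fraction": incid / comp if comp else float("nan"),
                "any_reversal": incid > 0,
            }
        )
    return pd.DataFrame(rows, columns=["char_id", "incidences", "comparisons", "fraction", "any_reversal"])


def reversal_mechanism_correlation(
    reversals: pd.DataFrame, per_char_mech: pd.DataFrame
) -> dict:
    """OLS R² of per-character convergence and parallelism proportions on the
    per-character reversal fraction."""
    merged = reversals.merge(per_char_mech, on="char_id")
    merged = merged[merged["n_pairs"] > 0].copy()
    if len(merged) < 3:
        raise ValueError("need at least three characters with defined values")
    x = merged["fraction"].to_numpy(float)
    if np.allclose(x.std(), 0.0):
        raise ValueError("reversal fractions have zero variance")
    out = {}
    for mech in ("convergence", "parallelism"):
        y = merged[mech].to_numpy(float) / merged["n_pairs"].to_numpy(float)
        if np.allclose(y.std(), 0.0):
            out[f"r2_{mech}"] = 0.0
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        out[f"r2_{mech}"] = r * r
    out["n_chars"] = int(len(merged))
    return out
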