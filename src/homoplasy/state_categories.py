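"""Five-way categorisation of character states from a resolved reconstruction.

Every state of every character (its root state plus every state reached by a
change) falls into exactly one category:

* ``nonhomoplastic_root`` — the root state, never re-derived;
* ``homoplastic_root`` — the root state, secondarily derived at least once;
* ``homoplastic_derived`` — a non-root state derived two or more times;
* ``synapomorphic`` — derived once, shared by at least two terminal taxa;
* ``autapomorphic`` — derived once, present in a single terminal taxon.

A sixth bookkeeping bucket, ``transient_apomorphic``, holds states derived
once but absent from every (non-missing) tip — possible under ACCTRAN when a
gain is immediately reversed — and is reported separately so the
synapomorphic/autapomorphic tallies stay comparable.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .core import MISSING
from .parsimony import Reconstruction

CATEGORIES = (
    "nonhomoplastic_root",
    "homoplastic_root",
    "homoplastic_derived",
    "synapomorphic",
    "autapomorphic",
    "transient_apomorphic",
)

ROOT_CATEGORIES = ("nonhomoplastic_root", "homoplastic_root")


def categorize(rec: Reconstruction) -> pd.DataFrame:
    """One row per (character, state) with derivation counts and category.

    ``n_tips`` counts only non-missing terminal observations; reconstructed
    states of missing tips never contribute.
    """
    matrix = rec.matrix
    ids = list(matrix.char_meta["id"])
    rows = []
    for j in range(rec.n_chars):
        root_state = rec.root_state(j)
        derivations = Counter(b for (_, _, _, b) in rec.changes[j])
        col = matrix.column(j)
        tip_counts = Counter(int(s) for s in col if s != MISSING)
        states = sorted(set(tip_counts) | set(derivations) | {root_state})
        for st in states:
            n_der = derivations.get(st, 0)
            n_tips = tip_counts.get(st, 0)
            at_root = st == root_state
            if at_root:
                cat = "homoplastic_root" if n_der >= 1 else "nonhomoplastic_root"
            elif n_der >= 2:
                cat = "homoplastic_derived"
            elif n_tips >= 2:
                cat = "synapomorphic"
            elif n_tips == 1:
                cat = "autapomorphic"
            else:
                cat = "transient_apomorphic"
            rows.append(
                {
                    "char_id": ids[j],
                    "state": st,
                    "n_derivations": n_der,
                    "n_tips": n_tips,
                    "at_root": at_root,
                    "category": cat,
                }
            )
    df = pd.DataFrame(
        rows, columns=["char_id", "state", "n_derivations", "n_tips", "at_root", "category"]
    )
    return df


def category_summary(table: pd.DataFrame) -> dict:
    """Counts and proportions per category, split ancestral vs derived."""
    if table.empty:
        raise ValueError("empty category table")
    counts = {c: int((table["category"] == c).sum()) for c in CATEGORIES}
    main = table[table["category"] != "transient_apomorphic"]
    n_states = int(len(main))
    derived = main[~main["at_root"]]
    once = derived[derived["n_derivations"] == 1]
    out = {
        "counts": counts,
        "fractions": {c: counts[c] / n_states for c in CATEGORIES if c != "transient_apomorphic"},
        "n_states": n_states,
        "n_root_states": int(main["at_root"].sum()),
        "n_homoplastic_root": counts["homoplastic_root"],
        "n_derived_states": int(len(derived)),
        "n_once_derived": int(len(once)),
        "n_synapomorphic": counts["synapomorphic"],
        "n_autapomorphic": counts["autapomorphic"],
        "n_homoplastic_derived": counts["homoplastic_derived"],
        "n_transient": counts["transient_apomorphic"],
    }
    return out
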