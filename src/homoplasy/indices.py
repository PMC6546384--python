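"""Homoplasy indices: per-character ci/ri/rc/hi, ensemble CI/HI/RI, multi-tree
averages and a taxon-permutation null distribution.

Conventions follow standard cladistic usage: ci = m/s, hi = 1 - ci,
ri = (g - s)/(g - m), rc = ci * ri, with m the minimum conceivable steps,
s the observed steps and g the star-tree maximum.  ``r_ic`` assigns a value
of 1 to characters whose derived states are all autapomorphic (g = m), for
which ri itself is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CharacterMatrix, Phylogeny
from . import parsimony
from .parsimony import Reconstruction


# ---------------------------------------------------------------------------
# per-character statistics
# ---------------------------------------------------------------------------

def character_stats(rec: Reconstruction) -> pd.DataFrame:
    """Per-character m, s, g, ci, hi, ri, rc, r_ic and status flags.

    ci is NaN (flagged ``invariant``) when s = 0; ri is NaN when g = m.
    ``autapomorphic_only`` marks characters whose non-modal states are all
    single-taxon (g = m with at least two states): these take r_ic = 1.
    """
    m = rec.m.astype(float)
    s = rec.s.astype(float)
    g = rec.g.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(s > 0, m / np.where(s > 0, s, 1), np.nan)
        ri = np.where(g > m, (g - s) / np.where(g > m, g - m, 1), np.nan)
    hi = 1.0 - ci
    rc = ci * ri
    invariant = rec.m == 0
    aut_only = (rec.g == rec.m) & (rec.m > 0)
    r_ic = np.where(aut_only, 1.0, ri)
    return pd.DataFrame(
        {
            "char_id": list(rec.matrix.char_meta["id"]),
            "m": rec.m,
            "s": rec.s,
            "g": rec.g,
            "ci": ci,
            "hi": hi,
            "ri": ri,
            "rc": rc,
            "r_ic": r_ic,
            "invariant": invariant,
            "autapomorphic_only": aut_only,
            "uninformative": rec.g <= rec.m,
        }
    )


# ---------------------------------------------------------------------------
# ensemble indices
# ---------------------------------------------------------------------------

def ensemble_from_counts(
    m: np.ndarray, s: np.ndarray, g: np.ndarray, exclude_uninformative: bool = False
) -> dict:
    """Ensemble CI = sum(m)/sum(s), RI = (sum(g)-sum(s))/(sum(g)-sum(m)), HI = 1-CI."""
    m = np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)
    g = np.asarray(g, dtype=float)
    if exclude_uninformative:
        keep = g > m
        m, s, g = m[keep], s[keep], g[keep]
    S, M, G = s.sum(), m.sum(), g.sum()
    if S == 0:
        raise ValueError("all characters invariant: ensemble CI undefined")
    ci = M / S
    ri = (G - S) / (G - M) if G > M else float("nan")
    return {"CI": ci, "HI": 1.0 - ci, "RI": ri, "sum_m": M, "sum_s": S, "sum_g": G}


def ensemble(rec: Reconstruction, exclude_uninformative: bool = False) -> dict:
    return ensemble_from_counts(rec.m, rec.s, rec.g, exclude_uninformative)


@dataclass
class MultiTreeIndices:
    """Ensemble indices per tree plus their mean and SD, and per-character means."""

    per_tree: pd.DataFrame  # columns tree, CI, HI, RI
    per_char_mean: pd.DataFrame  # char_id, mean ci/ri/r_ic/hi over trees

    @property
    def summary(self) -> dict:
        out = {}
        for col in ("CI", "HI", "RI"):
            out[col] = float(self.per_tree[col].mean())
            out[f"{col}_sd"] = float(self.per_tree[col].std(ddof=1)) if len(self.per_tree) > 1 else 0.0
        out["n_trees"] = int(len(self.per_tree))
        return out


def average_over_trees(
    matrix: CharacterMatrix,
    trees: list[Phylogeny],
    model: str = parsimony.ACCTRAN,
    exclude_uninformative: bool = False,
) -> MultiTreeIndices:
    """Reconstruct on every tree; report per-tree ensembles and per-character means.

    Mirrors averaging homoplasy indices over a posterior sample of topologies
    to absorb topological uncertainty.
    """
    if not trees:
        raise ValueError("need at least one tree")
    rows = []
    per_char = []
    for i, tree in enumerate(trees):
        rec = parsimony.reconstruct(tree, matrix, model)
        ens = ensemble(rec, exclude_uninformative)
        rows.append({"tree": i, "CI": ens["CI"], "HI": ens["HI"], "RI": ens["RI"]})
        stats = character_stats(rec)
        stats["tree"] = i
        per_char.append(stats)
    per_tree = pd.DataFrame(rows)
    allstats = pd.concat(per_char, ignore_index=True)
    per_char_mean = (
        allstats.groupby("char_id", sort=False)[["ci", "hi", "ri", "rc", "r_ic", "m", "s", "g"]]
        .mean()
        .reset_index()
    )
    return MultiTreeIndices(per_tree, per_char_mean)


# ---------------------------------------------------------------------------
# taxon-permutation null
# ---------------------------------------------------------------------------

def permutation_null(
    matrix: CharacterMatrix,
    tree: Phylogeny,
    n_perm: int,
    seed: int,
    exclude_uninformative: bool = False,
    chunk: int = 500,
) -> dict:
    """Null distribution of the ensemble homoplasy index HI.

    Each replicate permutes the taxon <-> matrix-row assignment uniformly at
    random and recomputes ensemble HI on the fixed tree (m and g are
    permutation-invariant, so only the tree lengths are recomputed).  Returns
    the null replicates, their mean/SD, the observed HI, and the fraction of
    replicates at or below the observed value (empirical percentile).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    n_chars = matrix.n_chars
    m = np.array([parsimony.min_steps(matrix.column(j)) for j in range(n_chars)])
    g = np.array([parsimony.max_steps(matrix.column(j)) for j in range(n_chars)])
    if exclude_uninformative:
        keep = np.where(g > m)[0]
        sub = CharacterMatrix(matrix.taxa, matrix.states[:, keep],
                              matrix.char_meta.iloc[keep].reset_index(drop=True))
        m = m[keep]
    else:
        sub = matrix
    M = float(m.sum())
    identity = np.arange(matrix.n_taxa)[None, :]
    S_obs = float(parsimony.bulk_lengths(tree, sub, identity)[0])
    if S_obs == 0:
        raise ValueError("all characters invariant: HI undefined")
    observed = 1.0 - M / S_obs

    null_hi = np.empty(n_perm, dtype=float)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        orders = np.stack([rng.permutation(matrix.n_taxa) for _ in range(b)])
        S = parsimony.bulk_lengths(tree, sub, orders).astype(float)
        null_hi[done : done + b] = 1.0 - M / S
        done += b
    return {
        "observed_hi": observed,
        "null_hi": null_hi,
        "null_mean": float(null_hi.mean()),
        "null_sd": float(null_hi.std(ddof=1)) if n_perm > 1 else 0.0,
        "fraction_leq_observed": float(np.mean(null_hi <= observed)),
        "n_perm": int(n_perm),
    }
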