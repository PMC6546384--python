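"""Discrete character-state coding of raw measurements and verbal colors.

Numeric traits are clustered by Ward agglomeration on Euclidean distance of
the raw values (no standardisation); the number of states is chosen by a
majority vote of five cluster-validity indices (silhouette, Calinski-Harabasz,
Davies-Bouldin, Dunn, gap statistic) over k = 2..k_max, with ties broken
toward fewer states.  Verbal colors are first mapped to RGB, projected on
their first two principal components, and clustered the same way; the
resulting color states are shared by every color character.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .core import MISSING, CharacterMatrix

VALIDITY_INDICES = ("silhouette", "calinski_harabasz", "davies_bouldin", "dunn", "gap")


def summarize_range(minimum: float, maximum: float) -> float:
    """Summarise a recorded (min, max) range by the average of the extremes."""
    if minimum > maximum:
        raise ValueError(f"range minimum {minimum} exceeds maximum {maximum}")
    return 0.5 * (minimum + maximum)


@dataclass
class CodingResult:
    """Chosen state count, per-sample state codes, and per-index votes."""

    char_id: str
    k: int
    labels: dict  # sample -> state code 0..k-1
    votes: dict = field(default_factory=dict)  # validity index -> voted k


# ---------------------------------------------------------------------------
# cluster-validity panel
# ---------------------------------------------------------------------------

def _dunn_index(dist: np.ndarray, labels: np.ndarray) -> float:
    """Min inter-cluster distance over max intra-cluster diameter."""
    ks = np.unique(labels)
    diam = 0.0
    for c in ks:
        idx = np.where(labels == c)[0]
        if idx.size > 1:
            diam = max(diam, dist[np.ix_(idx, idx)].max())
    inter = np.inf
    for a in range(len(ks)):
        for b in range(a + 1, len(ks)):
            ia = np.where(labels == ks[a])[0]
            ib = np.where(labels == ks[b])[0]
            inter = min(inter, dist[np.ix_(ia, ib)].min())
    if diam == 0.0:
        return np.inf
    return inter / diam


def _within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(labels):
        pts = x[labels == c]
        if len(pts) > 1:
            w += ((pts - pts.mean(axis=0)) ** 2).sum()
    return w


def _ward_labels(x: np.ndarray, k_values) -> dict[int, np.ndarray]:
    link = linkage(x, method="ward", metric="euclidean")
    return {k: fcluster(link, t=k, criterion="maxclust") for k in k_values}


def _vote_k(x: np.ndarray, k_max: int, seed: int = 0, n_ref: int = 10) -> tuple[dict, dict]:
    """Evaluate the five-index panel for k = 2..k_max on data ``x`` (n, d)."""
    n = len(x)
    ks = [k for k in range(2, min(k_max, n - 1) + 1)]
    labelings = _ward_labels(x, ks)
    # drop k values Ward could not realise (duplicate points)
    ks = [k for k in ks if len(np.unique(labelings[k])) == k]
    if not ks:
        raise ValueError("no valid clusterings for k >= 2")
    dist = squareform(pdist(x))
    scores: dict[str, dict[int, float]] = {name: {} for name in VALIDITY_INDICES}
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    ref_logw = {k: [] for k in ks}
    for _ in range(n_ref):
        ref = rng.uniform(lo, hi, size=x.shape)
        ref_lab = _ward_labels(ref, ks)
        for k in ks:
            ref_logw[k].append(np.log(max(_within_dispersion(ref, ref_lab[k]), 1e-12)))
    for k in ks:
        lab = labelings[k]
        scores["silhouette"][k] = silhouette_score(x, lab)
        scores["calinski_harabasz"][k] = calinski_harabasz_score(x, lab)
        scores["davies_bouldin"][k] = -davies_bouldin_score(x, lab)  # lower is better
        scores["dunn"][k] = _dunn_index(dist, lab)
        logw = np.log(max(_within_dispersion(x, lab), 1e-12))
        scores["gap"][k] = float(np.mean(ref_logw[k]) - logw)
    votes = {}
    for name in VALIDITY_INDICES:
        sc = scores[name]
        best = max(sc.values())
        votes[name] = min(k for k in ks if sc[k] == best)  # tie -> smaller k
    return votes, labelings


def _majority(votes: dict) -> int:
    tally: dict[int, int] = {}
    for k in votes.values():
        tally[k] = tally.get(k, 0) + 1
    best = max(tally.values())
    return min(k for k, c in tally.items() if c == best)  # tie -> smaller k


# ---------------------------------------------------------------------------
# numeric traits
# ---------------------------------------------------------------------------

def optimal_k(values, k_max: int = 8, char_id: str = "trait", seed: int = 0) -> CodingResult:
    """Code a numeric trait by Ward clustering with a validity-index vote.

    ``values`` maps sample/taxon to a real value (NaN excluded); state codes
    are ordered by ascending cluster mean.  A constant vector yields a single
    state without a vote.
    """
    if isinstance(values, dict):
        names = list(values)
        vals = np.array([values[t] for t in names], dtype=float)
    else:
        vals = np.asarray(values, dtype=float)
        names = list(range(len(vals)))
    keep = np.isfinite(vals)
    names = [n for n, k_ in zip(names, keep) if k_]
    vals = vals[keep]
    if vals.size < 2:
        raise ValueError("need at least two observed values")
    if np.unique(vals).size == 1:
        return CodingResult(char_id, 1, {n: 0 for n in names}, {})
    if np.unique(vals).size < 3 or k_max < 2:
        # only two distinct values: a 2-state split needs no vote
        order = {v: i for i, v in enumerate(np.unique(vals))}
        return CodingResult(char_id, int(np.unique(vals).size),
                            {n: order[v] for n, v in zip(names, vals)}, {})
    x = vals.reshape(-1, 1)
    votes, labelings = _vote_k(x, k_max, seed=seed)
    k = _majority(votes)
    labels = _order_by_mean(vals, labelings[k])
    return CodingResult(char_id, k, dict(zip(names, labels)), votes)


def _order_by_mean(vals: np.ndarray, raw_labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 by ascending cluster mean of ``vals``."""
    ks = np.unique(raw_labels)
    means = [vals[raw_labels == c].mean() for c in ks]
    order = {int(ks[i]): rank for rank, i in enumerate(np.argsort(means, kind="stable"))}
    return np.array([order[int(c)] for c in raw_labels])


# ---------------------------------------------------------------------------
# colors
# ---------------------------------------------------------------------------

def code_colors(table: pd.DataFrame, k_max: int = 8, seed: int = 0) -> CodingResult:
    """Code verbal colors from their RGB values.

    ``table`` has columns ``name``, ``R``, ``G``, ``B`` (0-255).  RGB triples
    are projected on the first two principal components and Ward-clustered in
    that plane with the validity-index vote.  State codes are ordered by
    ascending mean brightness (R+G+B), which is invariant to the arbitrary
    sign of the principal components.
    """
    req = {"name", "R", "G", "B"}
    if not req.issubset(table.columns):
        raise ValueError(f"color table needs columns {sorted(req)}")
    if table["name"].duplicated().any():
        dup = sorted(table.loc[table["name"].duplicated(), "name"])
        raise ValueError(f"duplicate color name(s): {dup}")
    rgb = table[["R", "G", "B"]].to_numpy(float)
    if ((rgb < 0) | (rgb > 255)).any():
        raise ValueError("RGB channels must lie in 0..255")
    names = list(table["name"])
    if len(names) < 3:
        raise ValueError("need at least three colors")
    if np.unique(rgb, axis=0).shape[0] == 1:
        return CodingResult("color", 1, {n: 0 for n in names}, {})
    n_pc = min(2, int(np.linalg.matrix_rank(rgb - rgb.mean(axis=0))))
    pcs = PCA(n_components=n_pc).fit_transform(rgb)
    votes, labelings = _vote_k(pcs, k_max, seed=seed)
    k = _majority(votes)
    brightness = rgb.sum(axis=1)
    labels = _order_by_mean(brightness, labelings[k])
    return CodingResult("color", k, dict(zip(names, labels)), votes)


# ---------------------------------------------------------------------------
# recoding overrides
# ---------------------------------------------------------------------------

def recode_state(
    matrix: CharacterMatrix,
    char_id: str,
    rule: dict[int, int],
    taxa: list[str] | None = None,
    merge: bool = False,
) -> CharacterMatrix:
    """Remap state codes of one character, optionally for a taxon subset.

    ``rule`` maps old to new codes.  Restricting to ``taxa`` splits a state
    (biological recoding override); mapping two states onto one requires the
    explicit ``merge`` flag.  The rule domain must be observed states.
    """
    ids = list(matrix.char_meta["id"])
    if char_id not in ids:
        raise KeyError(f"unknown character id '{char_id}'")
    j = ids.index(char_id)
    col = matrix.column(j).copy()
    observed = set(int(s) for s in matrix.alphabet(j))
    unknown = set(rule) - observed
    if unknown:
        raise ValueError(f"rule maps unobserved state(s) {sorted(unknown)}")

    rows = range(matrix.n_taxa) if taxa is None else [matrix.taxa.index(t) for t in taxa]
    new_col = col.copy()
    for i in rows:
        if col[i] != MISSING and int(col[i]) in rule:
            new_col[i] = rule[int(col[i])]

    if not merge:
        # a collision exists if two distinct old codes end up equal
        out_of: dict[int, set[int]] = {}
        for i in range(matrix.n_taxa):
            if col[i] != MISSING:
                out_of.setdefault(int(new_col[i]), set()).add(int(col[i]))
        collided = {k: v for k, v in out_of.items() if len(v) > 1}
        if collided:
            raise ValueError(
                f"recoding merges states {collided} without merge=True"
            )
    states = matrix.states.copy()
    states[:, j] = new_col
    return CharacterMatrix(list(matrix.taxa), states, matrix.char_meta.copy())
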