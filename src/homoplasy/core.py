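"""Core in-memory containers: rooted phylogenies and discrete character matrices.

Node identifiers are post-order integers fixed at construction time, so every
downstream table (ancestral states, change lists, derivation records) can refer
to nodes stably across runs.  The root always carries the largest id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for missing / inapplicable observations ('?' or '-' in NEXUS).
MISSING: int = -1

STAGES = ("egg", "L1", "L2", "L3", "pupa", "adult")
ADULT_ORGANS = ("head", "thorax", "abdomen", "male_terminalia", "female_terminalia")


class Phylogeny:
    """A rooted tree with post-order integer node ids; polytomies allowed.

    Parameters
    ----------
    children :
        ``children[v]`` lists the child ids of node ``v`` (empty for leaves).
        Ids must be a valid post-order numbering: every child id is smaller
        than its parent's, and the root is ``n_nodes - 1``.
    taxon_of :
        Mapping from leaf id to taxon label (bijective over leaves).
    branch_lengths :
        Optional length of the edge above each node (root entry ignored).
    support :
        Optional per-node support values (e.g. posterior probabilities).
    """

    def __init__(
        self,
        children: Sequence[Sequence[int]],
        taxon_of: Mapping[int, str],
        branch_lengths: Sequence[float] | None = None,
        support: Mapping[int, float] | None = None,
    ) -> None:
        self.children: list[list[int]] = [list(c) for c in children]
        self.n_nodes = len(self.children)
        self.root = self.n_nodes - 1
        self.taxon_of: dict[int, str] = dict(taxon_of)
        self.support = dict(support) if support else {}
        self.branch_lengths = (
            np.asarray(branch_lengths, dtype=float) if branch_lengths is not None else None
        )
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        for v, kids in enumerate(self.children):
            for c in kids:
                if c >= v:
                    raise ValueError("node ids are not a post-order numbering")
                self.parent[c] = v
        n_roots = int(np.sum(self.parent == -1))
        if n_roots != 1:
            raise ValueError(f"tree must have exactly one root, found {n_roots}")
        leaves = [v for v in range(self.n_nodes) if not self.children[v]]
        if set(self.taxon_of) != set(leaves):
            raise ValueError("taxon_of must map exactly the leaf ids")
        if len(set(self.taxon_of.values())) != len(self.taxon_of):
            raise ValueError("duplicate taxon labels on leaves")
        self.leaf_of: dict[str, int] = {t: v for v, t in self.taxon_of.items()}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_nested(
        cls, nested, branch_lengths: bool = False
    ) -> "Phylogeny":
        """Build from nested tuples of leaf labels, e.g. ``(("A","B"),("C","D"))``."""
        children: list[list[int]] = []
        taxon_of: dict[int, str] = {}

        def rec(node) -> int:
            if isinstance(node, str):
                children.append([])
                taxon_of[len(children) - 1] = node
                return len(children) - 1
            kids = [rec(k) for k in node]
            children.append(kids)
            return len(children) - 1

        rec(nested)
        return cls(children, taxon_of)

    @classmethod
    def from_dendropy(cls, tree) -> "Phylogeny":
        """Convert a rooted dendropy Tree (unifurcations suppressed first)."""
        tree.suppress_unifurcations()
        children: list[list[int]] = []
        taxon_of: dict[int, str] = {}
        lengths: list[float] = []
        support: dict[int, float] = {}

        def rec(nd) -> int:
            kids = [rec(c) for c in nd.child_nodes()]
            children.append(kids)
            vid = len(children) - 1
            lengths.append(nd.edge.length if nd.edge.length is not None else np.nan)
            if not kids:
                if nd.taxon is None:
                    raise ValueError("leaf without taxon label")
                taxon_of[vid] = nd.taxon.label
            lab = getattr(nd, "label", None)
            if kids and lab not in (None, ""):
                try:
                    support[vid] = float(lab)
                except ValueError:
                    pass
            return vid

        rec(tree.seed_node)
        bl = np.asarray(lengths, dtype=float)
        has_bl = not np.all(np.isnan(bl[:-1]))
        return cls(children, taxon_of, bl if has_bl else None, support)

    # -- basic queries --------------------------------------------------------

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    @property
    def leaves(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.children[v]]

    @property
    def taxa(self) -> list[str]:
        """Taxon labels in leaf-id order."""
        return [self.taxon_of[v] for v in self.leaves]

    def postorder(self) -> range:
        return range(self.n_nodes)

    def parents_first(self) -> Iterator[int]:
        """Iterate nodes with every parent before its children."""
        return reversed(range(self.n_nodes))

    def depths(self) -> np.ndarray:
        """Number of edges from the root to each node (root = 0)."""
        d = np.zeros(self.n_nodes, dtype=np.int64)
        for v in self.parents_first():
            if v != self.root:
                d[v] = d[self.parent[v]] + 1
        return d

    def path_to_root(self, v: int) -> list[int]:
        """Nodes from ``v`` (inclusive) up to and including the root."""
        out = [v]
        while out[-1] != self.root:
            out.append(int(self.parent[out[-1]]))
        return out

    def to_newick(self, lengths: bool = True) -> str:
        def rec(v: int) -> str:
            if self.is_leaf(v):
                s = _quote(self.taxon_of[v])
            else:
                s = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
                if v in self.support:
                    s += repr(self.support[v])
            if (
                lengths
                and self.branch_lengths is not None
                and v != self.root
                and np.isfinite(self.branch_lengths[v])
            ):
                s += f":{self.branch_lengths[v]:.10g}"
            return s

        return rec(self.root) + ";"

    def prune_taxa(self, drop: Iterable[str]) -> "Phylogeny":
        """Return a copy with the given taxa removed (unifurcations collapsed)."""
        drop = set(drop)
        keep_leaves = [v for v in self.leaves if self.taxon_of[v] not in drop]
        if len(keep_leaves) < 2:
            raise ValueError("pruning would leave fewer than two leaves")
        keep = set(keep_leaves)
        # a node survives if >= 1 kept leaf below; collapse single-child chains
        nkeep = np.zeros(self.n_nodes, dtype=int)
        for v in self.postorder():
            nkeep[v] = 1 if (self.is_leaf(v) and v in keep) else sum(
                nkeep[c] > 0 for c in self.children[v]
            )

        children: list[list[int]] = []
        taxon_of: dict[int, str] = {}
        lengths: list[float] = []

        def rec(v: int, extra_len: float) -> int:
            own = (
                float(self.branch_lengths[v])
                if self.branch_lengths is not None and np.isfinite(self.branch_lengths[v])
                else 0.0
            )
            if self.is_leaf(v):
                children.append([])
                taxon_of[len(children) - 1] = self.taxon_of[v]
                lengths.append(own + extra_len)
                return len(children) - 1
            live = [c for c in self.children[v] if nkeep[c] > 0]
            if len(live) == 1:
                return rec(live[0], extra_len + own)
            kids = [rec(c, 0.0) for c in live]
            children.append(kids)
            lengths.append(own + extra_len)
            return len(children) - 1

        live_root = [c for c in self.children[self.root] if nkeep[c] > 0]
        if nkeep[self.root] == 1 and len(live_root) == 1:
            rec(live_root[0], 0.0)
        else:
            rec(self.root, 0.0)
        bl = np.asarray(lengths) if self.branch_lengths is not None else None
        return Phylogeny(children, taxon_of, bl)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {len(self.leaf_of)} leaves, {self.n_nodes} nodes>"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class CharacterMatrix:
    """Taxa x characters table of small integer state codes (MISSING = -1).

    ``char_meta`` is indexed 0..n_chars-1 with columns ``id``, ``label``,
    ``stage`` and ``organ``; adult characters carry one of the five organ
    labels, pre-adult characters carry organ ``none``.
    """

    taxa: list[str]
    states: np.ndarray
    char_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int16)
        if self.states.ndim != 2:
            raise ValueError("states must be 2-D (taxa x characters)")
        if len(self.taxa) != self.states.shape[0]:
            raise ValueError("taxa list does not match state-row count")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon label(s): {dup}")
        if self.char_meta is None:
            self.char_meta = default_char_meta(self.n_chars)
        if len(self.char_meta) != self.n_chars:
            raise ValueError("char_meta length does not match character count")
        self.validate_meta()

    def validate_meta(self) -> None:
        meta = self.char_meta
        bad_stage = set(meta["stage"].dropna()) - set(STAGES)
        if bad_stage:
            raise ValueError(f"unknown stage label(s): {sorted(bad_stage)}")
        adult = meta["stage"] == "adult"
        if (adult & (meta["organ"] == "none")).any() or (
            ~adult & (meta["organ"] != "none")
        ).any():
            raise ValueError("organ must be 'none' exactly for non-adult characters")
        bad_org = set(meta.loc[adult, "organ"]) - set(ADULT_ORGANS)
        if bad_org:
            raise ValueError(f"unknown organ label(s): {sorted(bad_org)}")

    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_chars(self) -> int:
        return self.states.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.states[:, j]

    def alphabet(self, j: int) -> np.ndarray:
        """Sorted distinct observed (non-missing) state codes of character ``j``."""
        col = self.states[:, j]
        return np.unique(col[col != MISSING])

    def n_states(self, j: int) -> int:
        return int(self.alphabet(j).size)

    def total_states(self) -> int:
        """Total state count over all characters (whole-matrix inventory size)."""
        return int(sum(self.n_states(j) for j in range(self.n_chars)))

    def subset_taxa(self, taxa: Sequence[str]) -> "CharacterMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return CharacterMatrix(list(taxa), self.states[idx, :], self.char_meta.copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.states, index=self.taxa, columns=list(self.char_meta["id"])
        )


def default_char_meta(n_chars: int, stage: str = "adult", organ: str = "head") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f"c{j + 1:04d}" for j in range(n_chars)],
            "label": [f"character {j + 1}" for j in range(n_chars)],
            "stage": stage,
            "organ": organ if stage == "adult" else "none",
        }
    )
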