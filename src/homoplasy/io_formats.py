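"""Reading and writing the files the pipeline touches.

NEXUS character matrices and newick/NEXUS tree files are parsed with dendropy;
metadata and result tables are plain TSV.  Loaders are deliberately forgiving
about which file carries what (matrix vs. trees) but strict about content:
dimension mismatches, undeclared symbols and duplicate taxa are hard errors
naming the offender.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core import MISSING, CharacterMatrix, Phylogeny, default_char_meta

log = logging.getLogger(__name__)

SYMBOLS = "012345678"


# ---------------------------------------------------------------------------
# character matrices
# ---------------------------------------------------------------------------

def read_character_matrix(path, meta_path=None) -> CharacterMatrix:
    """Read a NEXUS standard-data matrix (symbols 0-8, '?'/'-' missing).

    ``meta_path`` is an optional TSV with columns ``char_id``, ``stage``,
    ``organ`` joined to characters by position of ``char_id``.
    """
    path = Path(path)
    try:
        cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"{path}: not a parseable NEXUS character matrix: {exc}") from exc
    if len(cm) == 0 or cm.max_sequence_size == 0:
        raise ValueError(f"{path}: no characters")

    taxa = [t.label for t in cm.taxon_namespace]
    if len(set(taxa)) != len(taxa):
        dup = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValueError(f"{path}: duplicate taxon label(s): {dup}")

    n_chars = cm.max_sequence_size
    states = np.full((len(taxa), n_chars), MISSING, dtype=np.int16)
    for i, tax in enumerate(cm.taxon_namespace):
        seq = cm[tax]
        if len(seq) != n_chars:
            raise ValueError(
                f"{path}: taxon '{tax.label}' has {len(seq)} characters, expected {n_chars}"
            )
        for j, cell in enumerate(seq):
            sym = cell.symbol
            if sym in ("?", "-"):
                continue
            if sym not in SYMBOLS:
                raise ValueError(
                    f"{path}: undeclared symbol '{sym}' at taxon '{tax.label}', character {j + 1}"
                )
            states[i, j] = int(sym)

    meta = read_char_meta(meta_path, n_chars) if meta_path else default_char_meta(n_chars)
    return CharacterMatrix(taxa, states, meta)


def read_char_meta(meta_path, n_chars: int) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"char_id", "stage", "organ"}
    if not required.issubset(meta.columns):
        raise ValueError(f"{meta_path}: metadata needs columns {sorted(required)}")
    if len(meta) != n_chars:
        raise ValueError(
            f"{meta_path}: {len(meta)} metadata rows for {n_chars} characters"
        )
    out = pd.DataFrame(
        {
            "id": meta["char_id"].tolist(),
            "label": meta["label"].tolist() if "label" in meta else meta["char_id"].tolist(),
            "stage": meta["stage"].tolist(),
            "organ": meta["organ"].fillna("none").tolist(),
        }
    )
    return out


def write_character_matrix(matrix: CharacterMatrix, path, meta_path=None) -> None:
    """Write a NEXUS DATA block (and optionally the metadata TSV)."""
    path = Path(path)
    width = max(len(t) for t in matrix.taxa) + 2
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};\n")
        fh.write(f'    FORMAT DATATYPE=STANDARD SYMBOLS="{SYMBOLS}" MISSING=? GAP=-;\n')
        fh.write("    MATRIX\n")
        for i, taxon in enumerate(matrix.taxa):
            row = "".join(
                "?" if s == MISSING else SYMBOLS[s] for s in matrix.states[i]
            )
            fh.write(f"    {_nexus_label(taxon):<{width}} {row}\n")
        fh.write("    ;\nEND;\n")
    if meta_path is not None:
        meta = matrix.char_meta.rename(columns={"id": "char_id"})
        meta[["char_id", "label", "stage", "organ"]].to_csv(
            meta_path, sep="\t", index=False
        )


def _nexus_label(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path, outgroup: Iterable[str] | None = None, schema: str | None = None) -> Phylogeny:
    """Read a single tree, rerooting on the branch subtending ``outgroup``."""
    trees = read_trees(path, outgroup=outgroup, schema=schema)
    if len(trees) != 1:
        raise ValueError(f"{path}: expected one tree, found {len(trees)}")
    return trees[0]


def read_trees(path, outgroup: Iterable[str] | None = None, schema: str | None = None) -> list[Phylogeny]:
    """Read a newick or NEXUS tree file (possibly many trees), each rerooted."""
    path = Path(path)
    if schema is None:
        head = path.read_text(encoding="utf-8", errors="replace")[:200].lstrip().lower()
        schema = "nexus" if head.startswith("#nexus") else "newick"
    tl = dendropy.TreeList.get(path=str(path), schema=schema, preserve_underscores=True)
    if not tl:
        raise ValueError(f"{path}: no trees found")
    out = []
    for t in tl:
        out.append(_to_rooted(t, outgroup, path))
    return out


def _to_rooted(tree: dendropy.Tree, outgroup: Iterable[str] | None, path) -> Phylogeny:
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if outgroup:
        tree.is_rooted = True
        og = set(outgroup)
        unknown = og - labels
        if unknown:
            raise ValueError(f"{path}: outgroup taxa not in tree: {sorted(unknown)}")
        if og == labels:
            raise ValueError(f"{path}: outgroup cannot contain every taxon")
        taxa = [t for t in tree.taxon_namespace if t.label in og]
        if len(taxa) == 1:
            node = tree.find_node_with_taxon_label(taxa[0].label)
        else:
            node = tree.mrca(taxa=taxa)
        if node is tree.seed_node:
            # the "outgroup clade" spans the root: reroot on the complement
            comp = [t for t in tree.taxon_namespace if t.label in (labels - og)]
            node = comp_node = (
                tree.find_node_with_taxon_label(comp[0].label)
                if len(comp) == 1
                else tree.mrca(taxa=comp)
            )
            if comp_node is tree.seed_node:
                raise ValueError(
                    f"{path}: outgroup {sorted(og)} is not a clade and cannot root this tree"
                )
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
        tree.is_rooted = True
    elif not tree.is_rooted and len(tree.seed_node.child_nodes()) > 2:
        log.warning("%s: unrooted tree accepted as rooted at its basal polytomy", path)
    return Phylogeny.from_dendropy(tree)


def write_tree(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def write_trees(trees: Sequence[Phylogeny], path) -> None:
    Path(path).write_text(
        "".join(t.to_newick() + "\n" for t in trees), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# matrix/tree reconciliation and result tables
# ---------------------------------------------------------------------------

def align_tree_matrix(tree: Phylogeny, matrix: CharacterMatrix) -> Phylogeny:
    """Reconcile leaf labels with matrix taxa.

    Tree-only taxa are pruned with a logged warning; matrix-only taxa are a
    hard error (silent dropping of coded data is never acceptable).
    """
    tree_taxa = set(tree.leaf_of)
    mat_taxa = set(matrix.taxa)
    missing = mat_taxa - tree_taxa
    if missing:
        raise ValueError(f"matrix taxa absent from tree: {sorted(missing)}")
    extra = tree_taxa - mat_taxa
    if extra:
        log.warning("pruning %d tree taxa absent from matrix: %s", len(extra), sorted(extra))
        tree = tree.prune_taxa(extra)
    return tree


def write_table(records, path, columns: Sequence[str] | None = None) -> None:
    """Write a result table as tab-separated UTF-8 with one header line.

    ``records`` may be a DataFrame or an iterable of dicts; an empty input
    with explicit ``columns`` yields a header-only file.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records and columns is None:
            raise ValueError("empty records with no column specification")
        df = pd.DataFrame(records, columns=columns if columns is not None else None)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
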