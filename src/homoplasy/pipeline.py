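"""End-to-end orchestration: reconstruct -> indices / categories / mechanisms
/ reversals / permutation null / stage statistics, under both resolution
models, with every output written to one directory and summarised in a single
deterministic JSON file."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import group_stats, indices, io_formats, mechanisms, parsimony, state_categories

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated inputs and options of one pipeline run."""

    matrix_path: str
    tree_path: str
    out_dir: str
    meta_path: str | None = None
    trees_path: str | None = None  # optional posterior sample for averaging
    outgroup: list[str] = field(default_factory=list)
    models: tuple[str, ...] = parsimony.MODELS
    permutations: int = 1000
    seed: int = 0
    mechanism_mode: str = "pooled"
    autapomorphies: str = "include"
    exclude_uninformative: bool = False

    def validate(self) -> None:
        for name in ("matrix_path", "tree_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file: {p}")
        for name in ("meta_path", "trees_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file: {p}")
        for m in self.models:
            if m not in parsimony.MODELS:
                raise ValueError(f"unknown model '{m}'")
        if self.permutations < 0:
            raise ValueError("permutations must be >= 0")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; write result tables plus ``summary.json``.

    Returns the summary dict.  Any stage failure aborts with the stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_log(out / "run.log")
    log.info("run config: %s", asdict(config))

    stage = "load inputs"
    try:
        matrix = io_formats.read_character_matrix(config.matrix_path, config.meta_path)
        tree = io_formats.read_tree(config.tree_path, outgroup=config.outgroup or None)
        tree = io_formats.align_tree_matrix(tree, matrix)
        # out_dir is where the summary itself lives; leaving it out keeps
        # repeated runs of the same analysis byte-identical
        summary: dict = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items() if k != "out_dir"},
            "n_taxa": matrix.n_taxa,
            "n_chars": matrix.n_chars,
            "total_states": matrix.total_states(),
            "models": {},
        }
        for model in config.models:
            stage = f"reconstruction ({model})"
            rec = parsimony.reconstruct(tree, matrix, model)
            mkey = model.lower()
            mres: dict = {}
            io_formats.write_table(rec.change_table(), out / f"changes_{mkey}.tsv")
            io_formats.write_table(rec.node_state_table(), out / f"node_states_{mkey}.tsv")

            stage = f"indices ({model})"
            stats = indices.character_stats(rec)
            io_formats.write_table(stats, out / f"character_stats_{mkey}.tsv")
            mres["ensemble"] = _round(indices.ensemble(rec, config.exclude_uninformative))

            stage = f"state categories ({model})"
            cats = state_categories.categorize(rec)
            io_formats.write_table(cats, out / f"state_categories_{mkey}.tsv")
            mres["categories"] = state_categories.category_summary(cats)

            stage = f"mechanisms ({model})"
            recs = mechanisms.derivation_records(rec)
            mech = mechanisms.mechanism_proportions(recs, config.mechanism_mode)
            per_char_mech = mech.pop("per_char")
            io_formats.write_table(per_char_mech, out / f"mechanisms_{mkey}.tsv")
            mres["mechanisms"] = _round(mech)

            stage = f"reversals ({model})"
            rev = mechanisms.count_reversals(rec)
            io_formats.write_table(rev, out / f"reversals_{mkey}.tsv")
            mres["reversals"] = {
                "mean_fraction": _r(float(rev["fraction"].mean())),
                "n_reversal_free": int((~rev["any_reversal"]).sum()),
                "n_chars": int(len(rev)),
            }
            mres["reversal_correlations"] = _round(
                mechanisms.reversal_mechanism_correlation(rev, per_char_mech)
            )

            stage = f"stage statistics ({model})"
            meta = matrix.char_meta
            if set(meta["stage"]) - {None}:
                try:
                    mres["stage_stats"] = {
                        "kruskal_stages": _round(group_stats.stage_test(stats, meta)),
                        "regression": _round(group_stats.stage_regression(stats, meta)),
                    }
                    if (meta["stage"] == "adult").any():
                        mres["stage_stats"]["kruskal_organs"] = _round(
                            group_stats.organ_test(stats, meta)
                        )
                        mres["stage_stats"]["wilcoxon_terminalia"] = _round(
                            group_stats.terminalia_test(stats, meta)
                        )
                except ValueError as exc:
                    log.warning("stage statistics skipped: %s", exc)
            summary["models"][mkey] = mres

        if config.permutations:
            stage = "permutation null"
            null = indices.permutation_null(
                matrix, tree, config.permutations, config.seed,
                config.exclude_uninformative,
            )
            null.pop("null_hi")
            summary["permutation_null"] = _round(null)

        if config.trees_path:
            stage = "multi-tree averaging"
            trees = [
                io_formats.align_tree_matrix(t, matrix)
                for t in io_formats.read_trees(config.trees_path, outgroup=config.outgroup or None)
            ]
            multi = indices.average_over_trees(matrix, trees, config.models[0],
                                               config.exclude_uninformative)
            io_formats.write_table(multi.per_tree, out / "ensemble_per_tree.tsv")
            io_formats.write_table(multi.per_char_mean, out / "character_stats_tree_mean.tsv")
            summary["multi_tree"] = _round(multi.summary)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {stage}: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    log.info("pipeline complete: %s", out / "summary.json")
    return summary


def _setup_log(path: Path) -> None:
    root = logging.getLogger("homoplasy")
    for h in [h for h in root.handlers if isinstance(h, logging.FileHandler)]:
        root.removeHandler(h)
        h.close()
    handler = logging.FileHandler(path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root.setLevel(logging.INFO)
    root.addHandler(handler)


def _r(x):
    return round(float(x), 10) if isinstance(x, (float, np.floating)) else x


def _round(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            out[k] = _round(v)
        elif isinstance(v, (float, np.floating)):
            out[k] = _r(v)
        elif isinstance(v, (np.integer,)):
            out[k] = int(v)
        else:
            out[k] = v
    return out
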