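"""Synthetic data with known ground truth for every pipeline stage.

The generator produces a family-level morphological dataset of drosophilid
flies: a rooted ultrametric Yule tree over ~56 taxa; 490
unordered characters with 1-8 states laid out over six developmental stages
(egg 12, L1 13, L2 23, L3 26, pupa 46, adult 370) and five adult organs (head
78, thorax 90, abdomen 40, male terminalia 150, female terminalia 12);
equal-rates Mk (Jukes-Cantor-like) character evolution with stage- and
organ-dependent rate multipliers; completely-at-random (optionally blocked)
missing data; numeric traits from Gaussian mixtures; and verbal colors drawn
around the three main fly pigment anchors (dark melanin, yellow sclerotin,
pale sclerotin) in RGB space.

Default rate multipliers peak at mid-larval stages and are lowest for adults
and for terminalia, so the simulated per-stage retention profile reproduces a
developmental-hourglass pattern (mid stages most homoplastic) and terminalia
come out least homoplastic — the structure the pipeline is meant to detect.
Every change event is logged (TruthLog), so parsimony reconstructions can be
checked against the generating history.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import MISSING, CharacterMatrix, Phylogeny

#: Characters per stage in the full-scale preset.
FULLSCALE_STAGE_CHARS = {"egg": 12, "L1": 13, "L2": 23, "L3": 26, "pupa": 46, "adult": 370}
#: Adult characters per organ in the full-scale preset.
FULLSCALE_ORGAN_CHARS = {
    "head": 78, "thorax": 90, "abdomen": 40, "male_terminalia": 150, "female_terminalia": 12,
}
#: Hourglass profile: mid-development evolves fastest, adults slowest.
DEFAULT_STAGE_RATES = {"egg": 1.0, "L1": 1.4, "L2": 1.8, "L3": 1.8, "pupa": 1.3, "adult": 0.7}
#: Terminalia are the most conserved adult organs.
DEFAULT_ORGAN_RATES = {
    "head": 1.3, "thorax": 1.3, "abdomen": 1.3, "male_terminalia": 0.55, "female_terminalia": 0.55,
}
#: State-count distribution with mean ~3 and a rare invariant class, echoing
#: 1479 states over 490 characters with three invariable ones.
DEFAULT_STATE_WEIGHTS = {1: 0.006, 2: 0.394, 3: 0.28, 4: 0.15, 5: 0.08, 6: 0.05, 7: 0.025, 8: 0.015}

PIGMENT_ANCHORS = np.array(
    [[45.0, 35.0, 28.0],      # dark melanin (black/brown)
     [228.0, 195.0, 70.0],    # yellow sclerotin
     [240.0, 238.0, 228.0]],  # pale/white sclerotin
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the full-scale conditions."""

    n_taxa: int = 56
    birth_rate: float = 1.0
    n_chars_per_stage: dict = field(default_factory=lambda: dict(FULLSCALE_STAGE_CHARS))
    n_chars_per_organ: dict = field(default_factory=lambda: dict(FULLSCALE_ORGAN_CHARS))
    stage_rates: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_RATES))
    organ_rates: dict = field(default_factory=lambda: dict(DEFAULT_ORGAN_RATES))
    state_weights: dict = field(default_factory=lambda: dict(DEFAULT_STATE_WEIGHTS))
    base_rate: float = 0.1  # Mk events per unit branch length before multipliers
    missing_fraction: float = 0.15
    block_missing: bool = False
    seed: int = 0

    def scaled(self, factor: float) -> "SimulationConfig":
        """Scale the character counts down by ``factor`` (at least 1 per stage)."""
        stages = {s: max(1, round(n / factor)) for s, n in self.n_chars_per_stage.items()}
        organs = {o: max(1, round(n / factor)) for o, n in self.n_chars_per_organ.items()}
        adult = sum(organs.values())
        stages["adult"] = adult
        return replace(self, n_chars_per_stage=stages, n_chars_per_organ=organs)


@dataclass
class TruthLog:
    """Generating history: true node states and change events per character."""

    node_states: np.ndarray  # (n_chars, n_nodes)
    events: pd.DataFrame     # char_index, parent_node, child_node, from_state, to_state

    def n_events(self, j: int) -> int:
        return int((self.events["char_index"] == j).sum())


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Rooted ultrametric Yule tree with ``n_taxa`` leaves.

    Waiting times between successive splits while k lineages exist are
    Exponential(k * birth_rate); a final Exponential(n * birth_rate) stretch
    follows the last split, so the expected root-to-tip depth is
    sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_taxa < 3:
        raise ValueError("need at least three taxa")
    rng = np.random.default_rng(seed)
    # grow as a nested dict structure, then post-order number
    next_id = [0]

    class _N:
        __slots__ = ("children", "length", "label")

        def __init__(self):
            self.children = []
            self.length = 0.0
            self.label = None

    root = _N()
    active = []
    for _ in range(2):
        c = _N()
        root.children.append(c)
        active.append(c)
    while len(active) < n_taxa:
        dt = rng.exponential(1.0 / (birth_rate * len(active)))
        for a in active:
            a.length += dt
        idx = rng.integers(len(active))
        parent = active.pop(int(idx))
        for _ in range(2):
            c = _N()
            parent.children.append(c)
            active.append(c)
    dt = rng.exponential(1.0 / (birth_rate * len(active)))
    for a in active:
        a.length += dt
    # label leaves deterministically by left-to-right position
    counter = [0]

    def label(n):
        if not n.children:
            counter[0] += 1
            n.label = f"t{counter[0]:02d}"
        for c in n.children:
            label(c)

    label(root)
    children: list[list[int]] = []
    taxon_of: dict[int, str] = {}
    lengths: list[float] = []

    def build(n) -> int:
        kids = [build(c) for c in n.children]
        children.append(kids)
        lengths.append(n.length)
        if not kids:
            taxon_of[len(children) - 1] = n.label
        return len(children) - 1

    build(root)
    return Phylogeny(children, taxon_of, np.asarray(lengths))


# ---------------------------------------------------------------------------
# characters
# ---------------------------------------------------------------------------

def _char_layout(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    organ_pool: list[str] = []
    for organ, n in config.n_chars_per_organ.items():
        organ_pool.extend([organ] * n)
    if len(organ_pool) != config.n_chars_per_stage.get("adult", 0):
        raise ValueError("organ character counts must sum to the adult stage count")
    oi = 0
    j = 0
    for stage, n in config.n_chars_per_stage.items():
        for _ in range(n):
            organ = "none"
            if stage == "adult":
                organ = organ_pool[oi]
                oi += 1
            rows.append({"id": f"c{j + 1:04d}", "label": f"{stage} character {j + 1}",
                         "stage": stage, "organ": organ})
            j += 1
    return pd.DataFrame(rows)


def simulate_characters(
    tree: Phylogeny, config: SimulationConfig
) -> tuple[CharacterMatrix, TruthLog]:
    """Evolve unordered Mk characters along the tree, logging every event.

    Each character draws its state count from ``state_weights`` and evolves
    under an equal-rates Mk process: change events on a branch of length t are
    Poisson(rate * t), each picking a uniform different state.  The rate is
    ``base_rate`` times the stage (and, for adults, organ) multiplier.
    Missing cells are injected completely at random, or in taxon-block runs
    when ``block_missing`` is set.
    """
    rng = np.random.default_rng(config.seed)
    meta = _char_layout(config)
    n_chars = len(meta)
    if tree.branch_lengths is None:
        raise ValueError("character simulation needs branch lengths")
    ks = rng.choice(
        list(config.state_weights), size=n_chars,
        p=np.array(list(config.state_weights.values())) / sum(config.state_weights.values()),
    )
    node_states = np.zeros((n_chars, tree.n_nodes), dtype=np.int16)
    events = []
    order = list(tree.parents_first())
    for j in range(n_chars):
        k = int(ks[j])
        stage = meta.loc[j, "stage"]
        organ = meta.loc[j, "organ"]
        rate = config.base_rate * config.stage_rates[stage]
        if stage == "adult":
            rate *= config.organ_rates[organ]
        st = node_states[j]
        st[tree.root] = rng.integers(k) if k > 1 else 0
        for v in order:
            for c in tree.children[v]:
                s = int(st[v])
                if k > 1:
                    t = float(tree.branch_lengths[c])
                    n_ev = rng.poisson(rate * t)
                    for _ in range(n_ev):
                        new = int(rng.integers(k - 1))
                        if new >= s:
                            new += 1
                        events.append(
                            {"char_index": j, "parent_node": v, "child_node": c,
                             "from_state": s, "to_state": new}
                        )
                        s = new
                st[c] = s

    # tip observations + missingness
    leaf_ids = tree.leaves
    taxa = [tree.taxon_of[v] for v in leaf_ids]
    states = np.stack([node_states[:, v] for v in leaf_ids]).astype(np.int16)
    if config.missing_fraction > 0:
        if config.block_missing:
            # contiguous character blocks missing per taxon (structured gaps)
            for i in range(len(taxa)):
                n_miss = int(round(config.missing_fraction * n_chars))
                if n_miss:
                    start = int(rng.integers(n_chars))
                    idx = (np.arange(n_miss) + start) % n_chars
                    states[i, idx] = MISSING
        else:
            mask = rng.random(states.shape) < config.missing_fraction
            # never blank out a whole character
            for j in range(n_chars):
                if mask[:, j].all():
                    mask[int(rng.integers(len(taxa))), j] = False
            states[mask] = MISSING
    matrix = CharacterMatrix(taxa, states, meta)
    ev = pd.DataFrame(
        events, columns=["char_index", "parent_node", "child_node", "from_state", "to_state"]
    )
    return matrix, TruthLog(node_states, ev)


def simulate_dataset(config: SimulationConfig) -> tuple[Phylogeny, CharacterMatrix, TruthLog]:
    """Tree plus matrix plus truth in one call (seeded from ``config.seed``)."""
    tree = simulate_tree(config.n_taxa, config.birth_rate, seed=config.seed)
    matrix, truth = simulate_characters(tree, config)
    return tree, matrix, truth


# ---------------------------------------------------------------------------
# raw trait tables for the coding front end
# ---------------------------------------------------------------------------

def simulate_numeric_traits(
    n_taxa: int, k_true: int, separation: float = 6.0, seed: int = 0, within_sd: float = 1.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian-mixture trait values with known component memberships.

    Component means are ``separation * within_sd`` apart.  Returns a table of
    taxon, value and the true component index per taxon.
    """
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    comp = rng.integers(k_true, size=n_taxa)
    # ensure every component occurs
    comp[:k_true] = np.arange(k_true)
    rng.shuffle(comp)
    values = comp * separation * within_sd + rng.normal(0.0, within_sd, size=n_taxa)
    table = pd.DataFrame({"taxon": [f"t{i + 1:02d}" for i in range(n_taxa)], "value": values})
    return table, comp


def simulate_colors(
    n: int, anchors: np.ndarray | int = 3, spread: float = 12.0, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """RGB color table sampled around pigment anchors, channels clamped to 0-255.

    Returns the table (name, R, G, B) and the true anchor index per color.
    """
    if isinstance(anchors, (int, np.integer)):
        if anchors > len(PIGMENT_ANCHORS):
            raise ValueError("at most three built-in pigment anchors")
        anchors = PIGMENT_ANCHORS[:anchors]
    anchors = np.asarray(anchors, dtype=float)
    if n < len(anchors):
        raise ValueError("need at least one color per anchor")
    rng = np.random.default_rng(seed)
    comp = rng.integers(len(anchors), size=n)
    comp[: len(anchors)] = np.arange(len(anchors))
    rng.shuffle(comp)
    rgb = anchors[comp] + rng.normal(0.0, spread, size=(n, 3))
    clipped = np.clip(rgb, 0, 255)
    table = pd.DataFrame(
        {
            "name": [f"color_{i + 1:02d}" for i in range(n)],
            "R": np.round(clipped[:, 0]).astype(int),
            "G": np.round(clipped[:, 1]).astype(int),
            "B": np.round(clipped[:, 2]).astype(int),
        }
    )
    return table, comp


def expected_yule_depth(n_taxa: int, birth_rate: float = 1.0) -> float:
    """Analytic expected root-to-tip depth of :func:`simulate_tree`."""
    return sum(1.0 / (k * birth_rate) for k in range(2, n_taxa + 1))


def expected_yule_depth_var(n_taxa: int, birth_rate: float = 1.0) -> float:
    """Variance of the root-to-tip depth (sum of independent exponentials)."""
    return sum(1.0 / (k * birth_rate) ** 2 for k in range(2, n_taxa + 1))
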