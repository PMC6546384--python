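# Methods

This note records the model, the algorithmic choices, the defaults, and the
known limitations of the package. Everything here is implemented in
`src/homoplasy/` and exercised by `tests/`.

## Parsimony model

Characters are unordered (Fitch) multistate with unit change costs on a
rooted tree that may contain polytomies. The length of a character is
computed with Hartigan's generalisation of the Fitch pass: at each internal
node with `c` children, the cost contribution is `c` minus the maximal number
of children whose state sets share a state. Missing observations (`?` or `-`
in NEXUS, `-1` internally) are treated as fully ambiguous over the
character's observed alphabet; internal nodes are likewise restricted to the
observed alphabet, which never changes the optimum under unit costs.

**Step bounds.** For each character, `m` = (number of distinct observed
states) − 1 is the minimum conceivable length, and `g` = (number of observed
taxa) − (size of the largest state class) is the length on a star tree, the
maximum any tree can require.

**ACCTRAN/DELTRAN.** Among all most-parsimonious reconstructions the package
selects one by exact lexicographic dynamic programming, not by a greedy
second pass: the primary objective is the change count; the secondary
objective is the sum over change edges of the parent node's depth, which
ACCTRAN minimises (changes pulled toward the root, favouring reversals) and
DELTRAN maximises (changes pushed toward the tips, favouring parallelisms).
Remaining ties are broken toward the smallest state code, making the output
deterministic. The invariant `depth_sum(ACCTRAN) ≤ depth_sum(DELTRAN)` holds
by construction and is verified against brute-force enumeration of all
reconstructions on small trees in the test suite.

## Indices

Per character: `ci = m/s`, `hi = 1 − ci`, `ri = (g − s)/(g − m)`,
`rc = ci·ri`. `ci` is undefined for invariant characters (s = 0); `ri` is
undefined when `g = m`, which happens exactly when every non-modal state is a
single-taxon state. `r_ic` equals `ri` where defined and 1 for those
autapomorphy-only characters, so that analyses of retention can either
include them (`r_ic`) or drop them (`ri`).

Ensemble indices sum the counts first: `CI = Σm/Σs`,
`RI = (Σg − Σs)/(Σg − Σm)`, `HI = 1 − CI`. An `exclude_uninformative` option
drops characters with `g ≤ m` from the sums.

**Permutation null.** Each replicate permutes the assignment of matrix rows
to taxa uniformly at random and recomputes the ensemble HI on the fixed
tree. `m` and `g` are invariant under this permutation, so only tree lengths
are recomputed; a vectorised Hartigan pass over bit-mask state encodings
evaluates hundreds of replicates at once (10⁴ replicates on a 56 × 490
matrix take a few seconds). Reported: null mean, SD, and the fraction of
replicates at or below the observed HI.

**Multiple trees.** Ensemble indices can be averaged over a sample of
topologies (e.g. a posterior sample); per-character indices are averaged the
same way, and the per-tree SD is reported.

## State categories

Each (character, state) pair — the root state plus every state that appears
as the target of a change — falls into exactly one category: root states are
`nonhomoplastic_root` or, if re-derived at least once, `homoplastic_root`;
derived states are `homoplastic_derived` (≥ 2 derivations), `synapomorphic`
(one derivation, ≥ 2 observed tips) or `autapomorphic` (one derivation, one
observed tip). A bookkeeping bucket, `transient_apomorphic`, holds states
derived once but observed in no tip (possible under ACCTRAN when a gain is
immediately reversed); it is reported separately so the main five fractions
stay comparable across models.

## Pairwise mechanisms

For each (character, taxon) with an observed state, a derivation record
stores the current state, the *original* state it last changed from, the
node of that change, the node where the original state itself arose, and the
node the change edge departs from. Unordered species pairs are classified:

- equal current states: **inertia** (same change node — the state arose
  once), **parallelism** (independent derivations from equal originals),
  **convergence** (independent derivations from different originals);
- different current states: **divergence** (both changed, equal originals,
  and the two change edges depart from the same node), **disparity 1**
  (equal original values of independent origin), **disparity 2** (everything
  else).

The strict co-departure condition for divergence is deliberate. A looser
reading — "equal originals of common origin" — would classify roughly a
third of all different-state pairs as divergence, including every
unchanged-vs-derived pair. Under the strict rule, accelerated transformation
removes co-departures (one change is pulled above the shared node), so
divergence is essentially absent under ACCTRAN and rare under DELTRAN — an
asymmetry the test suite asserts.

Counting uses per-character combinatorial grouping (sums of C(n,2) over
signature classes, O(n) per character) and is cross-checked in the tests
against an explicit loop that classifies every pair individually.

**Reversals.** For each observed tip and each strict ancestor, the
comparison is a reversal incidence when the two share a state while some
node strictly between them differs. The per-character reversal fraction is
incidences over comparisons; the package also reports R² of per-character
convergence and parallelism proportions on the reversal fraction.

## Group statistics

Kruskal–Wallis (tie-corrected) across the six developmental stages and the
five adult organs; a two-sided rank-sum test of terminalia vs somatic adult
characters (W is the Mann–Whitney statistic of the first group, terminalia);
and OLS fits of the retention value on the stage code D (egg = 1 … adult =
6), linear vs quadratic, compared by full-likelihood Gaussian AIC
(`delta_aic = AIC_linear − AIC_quadratic`, positive favouring the
quadratic). The vertex `−b/(2c)` locates the extremum; a concave-up fit with
an interior vertex is the hourglass signature. Rank tests come from
`scipy.stats`, the OLS fits from `statsmodels`.

## Character coding

Numeric traits are clustered by Ward linkage on the raw values. The number
of states is chosen by majority vote of five cluster-validity indices —
silhouette, Calinski–Harabasz, Davies–Bouldin, Dunn, and the gap statistic
(uniform reference, 10 seeded draws) — over k = 2..k_max (default 8), ties
toward fewer states. Silhouette/CH/DB come from scikit-learn; Dunn and gap
are implemented here. State codes are ordered by ascending cluster mean.
Recorded ranges are summarised by the midpoint before clustering.

Verbal colors are mapped to RGB, projected on their first two principal
components, and clustered the same way; codes are ordered by ascending mean
brightness (R+G+B), which is invariant to the arbitrary sign of the
principal components.

`recode_state` applies explicit biological overrides: splitting a state for
a subset of taxa, or merging states (only with an explicit `merge=True`,
since merging loses information).

## Synthetic data

The generator is first-class, seeded, and logs its ground truth.

- **Trees.** Pure-birth (Yule) trees: while k lineages exist the next split
  waits Exponential(k·λ); a final Exponential(n·λ) stretch follows the last
  split. Expected root-to-tip depth is Σ_{k=2..n} 1/(kλ), which the tests
  verify against 1000 simulated trees.
- **Characters.** Equal-rates Mk: change events on a branch of length t are
  Poisson(rate·t), each picking a uniformly random different state. Every
  event is logged (`TruthLog`), so the reconstructed step count can be
  checked against the generating event count (parsimony is a lower bound).
- **Defaults (the study conditions).** 56 taxa; 490 characters laid out as
  egg 12, L1 13, L2 23, L3 26, pupa 46, adult 370 (head 78, thorax 90,
  abdomen 40, male terminalia 150, female terminalia 12); per-character
  state counts drawn with mean ≈ 3 and a rare invariant class; base rate 0.1
  events per unit branch length; 15 % missing data (completely at random, or
  in per-taxon blocks with `block_missing`).
- **Rate profile.** Stage multipliers peak at the mid-larval stages
  (egg 1.0, L1 1.4, L2 1.8, L3 1.8, pupa 1.3, adult 0.7) and adult organ
  multipliers slow the terminalia (somatic 1.3, terminalia 0.55). Under an
  equal-rates Mk model a higher rate strictly lowers retention, so this
  profile generates the two structures the statistics are designed to
  detect: a concave stage-vs-retention curve with an interior minimum
  (hourglass) and higher retention in terminalia than in somatic organs.
- **Trait/color tables.** Gaussian mixtures with known memberships for the
  numeric coder, and RGB samples around three pigment anchors (dark
  melanin, yellow sclerotin, pale) for the color coder.

**Realism limits.** The Mk process has no rate heterogeneity across lineages
and no correlation between characters; missingness is unrelated to the tree;
trees are ultrametric pure-birth. These are deliberate simplifications: the
generator exists to provide analytically checkable ground truth, not to
imitate any particular empirical dataset.

## Numerical and design choices

- Post-order integer node ids (children before parents, root last)
  throughout; all per-character work is array-based.
- Derived sub-seeds everywhere stay below 2³¹; identical seeds give
  byte-identical outputs, including `run-all`'s `summary.json` (floats
  rounded to 10 decimals, no timestamps, output directory not echoed).
- Matrix-only taxa (coded data without a tip) abort with an error;
  tree-only taxa are pruned with a logged warning.
- Problem sizes in tests and the acceptance script (56 × 490, 10⁴
  permutations, trees ≤ 8 taxa for exhaustive oracles) are the package's own
  choices, balancing statistical power against runtime.

## Limitations

- ACCTRAN/DELTRAN each give one resolution among possibly many; quantities
  that depend on change placement (state categories, mechanisms, reversals)
  are resolution-dependent by nature, which is why both are always reported.
- The permutation null permutes whole taxon rows, preserving the per-column
  state frequencies but not any character correlation structure.
- The cluster-validity vote can disagree with the generating state count
  when clusters overlap strongly; the tests quantify recovery only for
  well-separated mixtures.
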