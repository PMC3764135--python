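# Methods

`dmbn` infers a directed/undirected network among genetically perturbed
regulators (transcription factors, chromatin machinery components, kinases,
phosphatases) from the discrete differential-expression profiles of their
deletion-mutant strains.  This note records the model, the estimator
choices, and the limits of what the synthetic benchmark demonstrates.

## Input model

The sole data input is a genes × mutants matrix with entries in {−1, 0, +1}:
+1 for significant up-regulation in the mutant versus wild type, −1 for
significant down-regulation, 0 for no significant change.  DEG calling and
normalization are upstream concerns; a thresholding utility
(`discretize_expression`, defaults ±1.0 on log2 ratios, user-overridable) is
provided as a convenience, not as a reproduction of any particular calling
pipeline.  A regulator deleted in two datasets keeps two columns labeled
`GENE@dataset`; double deletions are labeled `GENE1+GENE2`.  Name collapsing
happens only at evaluation time.

## The DM kernel and its feature map

Deletion profiles are sparse: most genes do not respond to most deletions.
A similarity that rewards co-absence (the trivial discrete kernel
`1{x == y}`) therefore saturates near 1 for almost every pair of mutants.
The DM kernel scores a gene pair 1 only when both calls are +1 or both are
−1; shared silence contributes nothing.

The kernel factorizes exactly through the 2-dimensional indicator map
φ(x) = (1{x = +1}, 1{x = −1}).  All production computation happens in this
feature space: per mutant, an N × 2 centered feature block, and globally a
2R × 2R feature covariance computed in one O(N·R²) pass.  No N × N Gram
matrix is formed outside of test oracles, so scoring cost is independent of
the gene count beyond the covariance pass.

## KGV multi-information

Dependence among m mutant columns is measured by the kernel generalized
variance,

    J = −½ · log( det(R_κ) / det(D_κ) )   (nats),

where R_κ is the 2m × 2m block **correlation** matrix of the centered
features with ridge κ·I added, and D_κ its block diagonal.  J ≥ 0, equals 0
for a single variable, and grows with dependence.

Two numerical choices matter:

* **Ridge on the correlation scale.**  The indicator variances are
  p(1 − p) for DEG density p — about 0.03 at realistic sparsity.  A ridge
  applied to the raw covariance at κ = 0.01 would be a third of the signal
  variance and visibly suppresses explaining-away: conditioning two
  co-regulated mutants on their common regulator then leaves tens of nats
  of residual dependence.  Standardizing features to unit variance before
  regularizing makes κ dimensionless and keeps conditioning sharp.
  Zero-variance features (a call never observed in a column) carry the
  ridge alone.  Default κ = 0.01, exposed as `--kappa`.
* **Exact low-rank identity.**  The N-dimensional formulation with
  regularized centered Grams of the standardized feature map equals the
  feature-space value exactly (Sylvester's determinant identity applied
  per block); the test suite verifies agreement to 1e−8 over random
  instances.  The Gram route is kept solely as that oracle.

## Network score

Local score of child x with parents Pa:

    score(x | Pa) = N · ( J({x} ∪ Pa) − J(Pa) ) − ω · (4·|Pa|/2) · log N.

The first term is the kernel analogue of a fitted log-likelihood gain; the
second is a BIC penalty in which every parent contributes d = 4 parameters —
the 2 × 2 cross-covariance block between two 2-dimensional feature maps.
Charging the full block dimension is essential on this data: for an
irrelevant candidate parent the empirical null of N·ΔJ is inflated well
beyond the classical χ² scale because residual variance clusters on the few
responsive genes (measured null mean ≈ 5 nats with tails to ≈ 30 at
N = 2000), and a 1-parameter penalty admits spurious edges at every ω of
practical interest.  With d = 4 the ω = 2 threshold (≈ 30 nats) cleanly
separates planted edges (10²–10³ nats) from the null.  ω is the sparsity
knob: raising it monotonically prunes the network.  The network score is
the sum of local scores; the empty graph scores exactly 0.

## Template

Per-mutant target lists (the nonzero genes of a column) induce a binary
R × R permission matrix: mutual regulator-DEG membership → both directions
allowed; one-way membership → only regulator → target allowed; otherwise a
sign-insensitive overlap of target lists allows an undirected pair; else
the pair is forbidden.  Double deletions match membership through either
constituent gene.  One-way pairs double as background causal knowledge for
the PDAG step.  `--template none` disables constraints (every off-diagonal
pair allowed), matching the template-free analyses.

## Search

Greedy-ascent TABU search from the empty graph over add/delete/reverse
moves, all template-consistent and acyclicity-safe.  Each step applies the
single highest-gain legal move (possibly negative); the inverse of an
applied move is tabu for `tabu_tenure` = 10 moves unless it beats the best
score seen (aspiration).  Stopping: `patience` = 20 non-improving moves or
10·R² moves.  Acyclicity is answered by an incremental reachability
structure (O(R²) updates on additions, recomputation on deletions), which
the suite validates against fresh depth-first search over random move
sequences.  Ties are broken lexicographically (add < delete < reverse, then
parent, then child), so results are deterministic for a fixed
configuration; mutants with no DEGs remain isolated by construction and are
skipped during move generation.  Local scores are cached by (child, parent
set).

## Causal interpretation

The learned DAG is reduced to compelled (directed) and non-compelled
(undirected) edges: start from the skeleton, orient the DAG's v-structures,
impose the template's asymmetric pairs as background orientations (a
background pair whose edge is absent is ignored with a warning; one
contradicting a v-structure or the learned direction raises an error rather
than silently flipping), then close under Meek's rules R1–R4.  On ≤ 5-node
graphs the result is verified against brute-force enumeration: without
background, compelled status matches the Markov equivalence class exactly;
with background, it matches the set of consistent extensions.

## Evaluation statistics

Duplicate nodes from multiple datasets are collapsed to gene names first;
parallel edges merge to one interaction (conflicting or mixed orientations
become undirected).  Precision and recall match predictions against
reference pairs ignoring direction; the recall denominator counts only
reference pairs with both endpoints among network nodes.  Zero-denominator
cases are reported as NA, never as 0.  Orientation precision compares
compelled edges with a directed regulator → DEG reference (pair (A, B) iff
gene B is a DEG in A's deletion column) and carries an exact one-sided
binomial test against fair-coin orientation, computed with integer
arithmetic.  The Jaccard index baseline (|A∩B| / |A∪B| of target sets, 0
when both empty) and its thresholded network are included for comparison.
Functional enrichment of target lists uses the hypergeometric upper tail —
exact rational arithmetic for universes up to 10⁴ genes, log-space survival
function beyond — with Benjamini–Hochberg adjustment reported alongside raw
p-values; the universe defaults to all genes with a DEG call in any mutant.

## Synthetic benchmark

The generator plants a random DAG over R regulators (random topological
order, independent edges at probability 0.2 — about one edge per node on
ten regulators, typical of curated pathway modules) and gives each
regulator a Poisson(40)-sized signed direct-target set among the
non-regulator genes (signs 50/50).  Gene-level effects cascade along edges:
a regulator's realized program is its direct targets plus, per direct
regulator, each element of that regulator's realized program independently
with probability 0.8 per step, signs preserved.  A regulated gene thus
mediates an attenuated copy of its regulators' programs, so a deletion
profile is predictable from the deletion profiles of the regulators above
it, colliders point regulator → target, and the planted DAG is the exact
conditional-independence structure of the columns.  Flip noise (probability
0.02 per entry, uniform replacement over {−1, 0, +1}) is injected into the
realized programs *inside* the cascade — propagating biological
stochasticity rather than terminal measurement error — which preserves that
Markov property; with terminal noise instead, conditioning on a corrupted
regulator column provably leaves residual dependence among its targets and
no learner could recover the planted skeleton cleanly.  Regulators are also
matrix rows: deleting r sets its own row to −1 and marks downstream
regulator rows as DEGs with the same cascading rule, which is what gives the
template its one-way orientations; these rows receive terminal entry noise.

Defaults (R = 10, N = 2000, 40 targets, decay 0.8, noise 0.02) produce
60–150 DEGs per column — the sparsity regime of real deletion-mutant
compendia.  What the benchmark does **not** emulate: correlated
array-level noise, dosage effects, double-deletion epistasis, condition
dependence of regulation, and chance sharing of targets between unrelated
regulators beyond the uniform-sampling rate.  Passing recovery tests
therefore demonstrates correctness of the estimator and search under the
model's assumptions, not performance on any particular real compendium.

At these settings the full pipeline recovers the planted network with mean
skeleton precision and recall above 0.95 over ten seeds and orients
essentially all compelled edges consistently with the regulator → DEG
reference; a ten-node chain at noise 0.05 is recovered exactly in all ten
seeds.  These are the quantities `scripts/acceptance.py` recomputes.

## Problem sizes and determinism

Test and acceptance workloads use R ≤ 10 regulators and N ≤ 2000 genes with
ten simulation seeds — sizes chosen so the whole suite re-runs in well under
a minute while exercising the same sparsity regime as the motivating data.
The acceptance script derives all simulation seeds from its `--seed`
argument; the search itself is deterministic given a configuration, and the
`seed` field of `SearchConfig` is reserved for optional randomized restarts
(off by default).

## Known limitations

* The KGV is a Gaussian surrogate on indicator features; it measures
  second-order dependence of the feature map, not full mutual information.
  Higher-order interactions among ≥ 3 regulators that leave pairwise
  feature covariances untouched are invisible to it.
* TABU search carries no optimality guarantee beyond the exhaustively
  verified 3-node case; very dense true networks with many near-ties may
  end in local optima.
* The template is built from the same matrix being scored, so systematic
  DEG-calling artifacts propagate into both the constraints and the score.
* `collapse_duplicates` treats a double-deletion label as a single node
  name; it does not distribute edges onto the constituent genes.
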