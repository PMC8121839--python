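# Methods

This note documents the models and procedures implemented in `celltree`,
the parameters that matter, the synthetic benchmark the tests run on, and
the design choices made where the design was genuinely open.

## The classification tree

Cell populations are organised in a rooted tree with uniquely named nodes.
The root is a synthetic node named `root`; it carries no classifier and is
excluded from ancestor sets (otherwise every prediction would share the root
with every truth and the hierarchical metrics would be inflated by a
constant).  A flat classifier is the special case of a depth-one tree.
Trees serialise to Newick with named internal nodes; branch lengths are
ignored on read and never written; child order is insertion order, so
serialisation is deterministic.  Nodes accumulate *synonyms* — labels under
which other datasets know the same population — which keeps every dataset's
original annotation recoverable after progressive learning.

## Local classifiers

Training data for node *n*:

* positives: cells labelled `n` or any descendant of `n`;
* negatives, *siblings policy*: cells labelled under any subtree of a
  sibling of `n` (same parent, parent excluded); when `n` has no siblings,
  cells labelled exactly as the parent.

Cells labelled with an internal node belong to that node and its ancestors
but to none of its children; with siblings present they never appear in a
child's negative set.

All nodes share one PCA of the training data (`n_components = 100`, capped
at the available rank).  Per node, a two-sided Welch two-sample *t*-test
compares positives and negatives on every component; components with
*p* < α/m are kept (α = 0.05, m = the realised component count — when the
data has fewer than 100 non-degenerate components the Bonferroni divisor
shrinks with it).  If nothing passes, the five smallest-*p* components are
kept, so the selection is never empty.  The Welch variant is used because
population sizes and variances differ wildly across nodes.

Two classifier kinds:

* `linear` — scikit-learn `LinearSVC` (squared hinge, L2 regularisation,
  tol 1e-4, max_iter 5000, fixed `random_state`), fitted on positives vs
  negatives.  Scores are divided by ‖w‖ so they are geometric distances to
  the hyperplane and comparable across sibling nodes.
* `one_class` — scikit-learn `OneClassSVM(nu=0.05)`, fitted on positives
  only.  ν bounds the fraction of training positives outside the boundary.
  The kernel defaults to RBF (the library default of the one-class SVM;
  exposed as `one_class_kernel` for users who want a linear boundary).
  Scores are the signed decision function, zero on the boundary.

Populations with fewer than two cells abort training with an explicit error:
a one-class boundary on a single point is meaningless, and tiny populations
degrade the one-class model severely.

## Reconstruction-error rejection

Unknown populations are absent when the PCA is learned, so they are poorly
represented by the retained components.  The per-cell reconstruction error
is the Euclidean distance between a cell and its projection onto the
component plane (project, invert, subtract).  The threshold is calibrated by
nested five-fold cross-validation: per fold, fit the PCA on the training
split, take the *q*-th percentile (default q = 0.99) of the held-out
errors; the threshold is the median of the five fold percentiles, and the
final projection is refitted on all data.  By construction ≈ 1 − q of
in-distribution cells exceed the threshold, which makes the false-negative
rate directly controllable through q.  `scripts/acceptance.py` measures
this rate on the default benchmark; it comes out at ≈ 1%.

The filter runs before any classifier is consulted, both at final
prediction and during the cross-prediction of tree learning.  The flag
`reject_reconstruction=False` disables it; this matters for stress tests
where one wants the classifiers alone to cope with unseen populations.

## Prediction walk

For an accepted cell the walk starts at the root: score all children;
if none claims the cell, emit the current node's name (or reject at the
root); if exactly one claims it, descend; if several do, descend into the
highest score.  Exact score ties fall to the first child in insertion
order, which keeps prediction deterministic.

## Reciprocal matching and tree updating

Cross-prediction produces confusion matrices (rows: true populations of one
dataset; columns: the other tree's node names plus `rejected`).  Rows are
normalised to fractions and binarised per row: rank descending, keep the
top fraction, keep walking while the gap to the preceding (higher) fraction
is strictly below the threshold (default 0.25); a zero fraction never
matches (a population to which no cells were assigned cannot be a match —
the ranking rule alone would allow it after a chain of sub-threshold gaps).
The matching matrix is X = BC1ᵀ + BC2 restricted to the
population-by-population block; matches to `rejected` and to prediction
columns without training cells stay in the binary matrices as bookkeeping
and drive new-population detection.

Scenario resolution applies, in order and to a fixed point: perfect
matches, splits, merges; then new populations; then, if nonzero entries
remain, X is made strict (every 1 that is not alone in both its row and
column is zeroed) and the sweep runs once more, accepting the surviving
isolated one-sided matches.  Whatever remains is a complex scenario: the
population is omitted from the tree with a warning, and its cells are
excluded from later pooled training.

Three deliberate generalisations, each forced by batch geometries that the
plain patterns cannot resolve:

* **Splits and merges accept one-sided members.**  A coarse population's
  cells spread unevenly over fine populations (e.g. one third / two thirds);
  the smaller fraction can fall below the binarisation threshold in one
  direction, leaving a 1 next to 2s.  Requiring at least one reciprocal 2
  while consuming the accompanying 1s recovers the intended split/merge.
* **Merges reduce to ancestry-maximal nodes.**  When a low-resolution
  population matches a node *and* that node's descendants, the descendants
  are absorbed and the new parent is inserted above the maximal set —
  unless a *single* matched ancestor covers everything, in which case the
  new population belongs *between* that ancestor and the matched
  descendants, and the rule recurses below it.
* **A lone reciprocal match with an internal node attaches as a child**
  (with a leaf it is a synonym).  An internal node denotes a broader
  population; a population that reciprocally matches it but none of its
  children is a refinement the current children do not cover.

New populations require reciprocal evidence: an all-zero row *and* the
incumbent classifier having matched the population to rejection.  An
all-zero row without rejection is reported as unmatched and omitted.

Name collisions when attaching (a dataset re-uses a name the tree already
holds for a different node) are resolved by suffixing ` (2)`, ` (3)`, ...;
matching is label-agnostic so this is cosmetic.

## Progressive learning

Iteration 1 trains flat classifiers on the first two datasets,
cross-predicts, matches and updates the first tree.  Iteration *k* trains a
flat classifier on the new dataset and the current tree on all previous
datasets pooled, their labels rewritten to tree node names through the
per-dataset label maps; then matches and updates again.  The final
classifier is retrained on everything pooled.

## Evaluation

Hierarchical precision/recall/F1 over ancestor sets (root excluded;
a rejected cell contributes an empty predicted set, so rejection costs
recall but not precision).  Median F1 is the median per-population F1 after
removing cells with rejected or internal predictions.  The k-fold harness
stratifies folds by population with a user seed and reports, per fold, the
hierarchical metrics plus the fractions of rejected and internal
predictions.

## Synthetic benchmark

The generator emulates hierarchically structured scRNA-seq counts at the
statistical level.  Every branch of a ground-truth tree carries a sparse set
of DE genes (probability `de_prob = 0.1` per gene) with multiplicative
log-normal factors (|log-factor| ~ N(1.0, 0.4), random direction); a leaf's
profile is a shared log-normal baseline times the product of factors along
its path, so siblings share the DE genes of their common ancestors and
population similarity decays with tree distance.  Counts are gamma-Poisson
(dispersion 0.1) with log-normal library sizes (mean 20 000, σ = 0.2), and
the output is log2(count + 1).

The default benchmark has six leaf populations of 1500 cells each under the
three-level tree

    (Group1,Group2,Group3,(Group4,(Group5,Group6)Group56)Group456)root;

with 2000 genes — enough genes for realistic PCA behaviour while keeping
runtimes short.  The default effect sizes make the populations widely
separated: a flat linear classifier exceeds 99% held-out leaf accuracy.
Batches at three annotation resolutions are derived by partitioning the
cells and relabelling: batch 1 merges everything under Group456, batch 2
merges Group5/Group6 into Group56, batch 3 keeps full resolution.

What the generator does *not* emulate: batch effects (alignment is upstream
and out of scope), doublets, ambient RNA, and dropout beyond what the
negative-binomial sparsity produces.  Tests passing on this benchmark
demonstrate the correctness of the machinery — matching, tree edits,
calibration — under clean separations; they do not certify performance on
real tissues, where population boundaries are soft and annotations are
partly wrong.

## Problem sizes used in the test suite

The tree-recovery tests run the full progressive loop at 240 cells per leaf
and 600 genes (all six batch orders × five simulation seeds, plus the
missing-population stress case in both resolution orders); the rejection
calibration test uses 400 cells per leaf and 800 genes over 20 seeds.
These sizes keep each scenario's statistical structure intact — batch
populations still hold ≥ 70 cells — while the whole suite runs in about two
minutes.  `scripts/acceptance.py` runs the calibration measurement at the
full default benchmark scale (6 × 1500 cells, 2000 genes, 20 seeds).

## Known limitations

* The one-class kind is sensitive to small populations; populations of a
  handful of cells will be claimed poorly or not at all.
* Scenario resolution is greedy and deterministic; pathological matching
  matrices (dense blocks of reciprocal matches) degrade to complex
  scenarios rather than searching for a globally optimal edit sequence.
* Labels are trusted: systematically mislabelled populations produce trees
  that faithfully reflect the mislabelling.
* The reconstruction filter assumes the training data's principal subspace
  is informative; if new populations lie inside it, only the one-class
  boundaries can reject them.
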