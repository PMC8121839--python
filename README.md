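# celltree

Hierarchical progressive learning of cell identities from annotated
single-cell RNA-seq datasets.

## The problem

Single-cell datasets are annotated at wildly different resolutions: one lab
publishes "T cells", another distinguishes CD4+ naive from CD4+ memory T
cells, and no shared nomenclature connects the two.  A classifier that wants
to learn from *both* datasets needs (i) a hierarchy that can represent
populations at several resolutions, (ii) a way to discover how the labels of
different datasets relate to each other without trusting the label text, and
(iii) a rejection option for populations it has never seen.

`celltree` addresses all three.  It maintains a **classification tree** of
cell populations, trains a local classifier for every node except the root,
and grows the tree **progressively**: each new annotated dataset is matched
against the current tree by reciprocal cross-prediction, and the matches are
turned into tree edits (perfect match, split, merge, new population).
Datasets must share one batch-aligned expression space; the alignment itself
(Seurat, Harmony, scArches, ...) is upstream of this package.

## The method in brief

**Local classifiers.**  For a node *n*, positive training cells are those
labelled with *n* or any of its descendants; negatives follow the *siblings
policy* (cells labelled under any sibling subtree; with no siblings, cells
labelled as the parent itself).  Classifiers operate on the first 100
principal components of the training data; each node keeps only the
components that separate its positives from its negatives (two-sided Welch
*t*-test, Bonferroni-corrected α = 0.05, falling back to the five smallest
*p*-values when nothing passes).  Two classifier kinds are available: an
L2-regularised linear SVM (higher accuracy) and a one-class SVM with
ν = 0.05 fitted on positives only (better novelty rejection).

**Rejection.**  A cell is rejected outright when its *reconstruction error*
— the distance to the plane spanned by the retained principal components —
exceeds a threshold calibrated by nested five-fold cross-validation as the
median across folds of the *q*-th percentile (default *q* = 0.99) of
held-out errors, so roughly 1 − *q* ≈ 1% of in-distribution cells are
falsely rejected.  Otherwise prediction walks the tree top-down: all
children negative ⇒ internal-node label (or rejection at the root); one or
more positive ⇒ descend into the highest-scoring child.

**Matching.**  Given two labelled datasets with trained trees, each
classifier predicts the other dataset's cells, yielding confusion matrices
C1, C2.  Rows are normalised, `NC_ij = C_ij / Σ_j C_ij`, and binarised: per
row the top fraction matches, and further fractions match while the gap to
the preceding (higher) fraction stays below 0.25.  The matching matrix

    X = BC1ᵀ + BC2

has entries 2 (reciprocal match), 1 (one-sided) or 0, and drives tree edits:
a lone reciprocal entry is a perfect match; several populations matching a
single node split it; one population matching several sibling nodes merges
them under a new parent; a population matched only to rejection becomes a
new child of the root.  Remaining ambiguity triggers a strict reciprocal
second pass; what still cannot be placed is reported and omitted.

**Evaluation.**  The hierarchical F1-score credits partially correct
predictions through ancestor sets: hP = Σ|Pᵢ∩Tᵢ|/Σ|Pᵢ|,
hR = Σ|Pᵢ∩Tᵢ|/Σ|Tᵢ|, HF1 = 2·hP·hR/(hP+hR); the median F1-score is the
median per-population F1 after discarding rejected and internal predictions.

## Worked example

```python
import numpy as np
from celltree import (SimConfig, simulate_hierarchical_counts, derive_batches,
                      ProgressiveTreeLearner, hierarchical_f1, DEFAULT_BATCHES)

# six populations, known 3-level hierarchy, three batches annotated at
# coarse / medium / full resolution
ds, truth = simulate_hierarchical_counts(SimConfig(n_genes=600, cells_per_leaf=240, seed=7))
batches = derive_batches(ds, truth, DEFAULT_BATCHES, seed=7)

learner = ProgressiveTreeLearner(kind="linear").fit(
    [(b.X, b.labels) for b in batches]
)
print(learner.tree_.to_newick())
pred = learner.classifier_.predict(ds.X)
print(hierarchical_f1(ds.labels, pred, learner.tree_))
```

prints

```
(Group1,Group2,Group3,(Group4,(Group5,Group6)Group56)Group456)root;
(1.0, 1.0, 1.0)
```

The learned Newick tree is exactly the ground-truth hierarchy: batch 1 only
knew the coarse "Group456", batch 2 refined it into Group4 + Group56, and
batch 3 split Group56 into Group5 and Group6 — the reciprocal matching
stitched the three annotation levels back together.  The final classifier
then labels the (training) dataset perfectly; on held-out cells expect a
hierarchical recall just below 1, since the reconstruction filter falsely
rejects ≈ 1% of fresh in-distribution cells by design at q = 0.99.

The same workflow is available from the shell:

```bash
celltree simulate --seed 7 --out-matrix X.tsv --out-labels l.tsv --out-tree t.nwk
celltree train --data X.tsv --labels l.tsv --tree t.nwk --kind linear --out model.bin
celltree predict --model model.bin --data Y.tsv --out pred.tsv
celltree learn --datasets d1.tsv:l1.tsv,d2.tsv:l2.tsv --out tree.nwk
celltree evaluate --true l.tsv --pred pred.tsv --tree tree.nwk --out metrics.json
```

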