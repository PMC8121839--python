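"""Convert a matching matrix into classification-tree edits.

The matching matrix ``X`` (rows: populations of the newly added dataset D2,
columns: populations of the incumbent tree's dataset D1) is resolved into
scenarios and applied to the tree:

perfect match
    A lone reciprocal entry between a D2 population and a D1 *leaf*; the leaf
    keeps its incumbent name and the D2 name is recorded as a synonym.  A lone
    reciprocal match with a D1 *internal* node attaches the D2 population as a
    new child instead (the internal node covers a broader population, so the
    reciprocally matching D2 population refines it).
split
    One D1 population matched by several D2 populations that match nothing
    else: D2 being annotated at higher resolution — the D2 populations become
    children of the D1 node.
merge
    One D2 population matched to several D1 populations that match nothing
    else: D2 is at lower resolution — the D2 population is inserted as a new
    parent of the matched nodes.  Matched nodes that are descendants of other
    matched nodes are absorbed into their ancestors first; the remaining
    (ancestry-maximal) nodes must be siblings, otherwise the scenario is
    complex.
new population
    A D2 population that matches nothing and whose cells were rejected by the
    incumbent classifier becomes a new child of the root.

A split or merge may also consume one-sided (value 1) entries in its own
column/row as long as at least one entry is a reciprocal 2; this covers the
common case where the coarse population's cells spread unevenly over the fine
populations and one direction of the match falls below the binarisation
threshold.

Scenarios are applied in the order perfect, split, merge (repeated to a fixed
point), then new populations.  If nonzero entries remain, X is made *strict*:
every 1 that is not the sole nonzero entry of both its row and its column is
zeroed, and the sweep runs once more accepting the surviving isolated
one-sided matches.  Whatever still remains is reported as a complex scenario
and the involved D2 populations are omitted from the tree with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matching import MatchResult
from .tree import ClassificationTree

logger = logging.getLogger(__name__)


@dataclass
class MatchScenario:
    """One resolved (or unresolvable) pattern of the matching matrix."""

    kind: str  # perfect | split | merge | new_population | unmatched | complex
    d1_populations: tuple
    d2_populations: tuple
    action: str = ""


@dataclass
class UpdateReport:
    """Outcome of one tree update."""

    scenarios: list[MatchScenario] = field(default_factory=list)
    #: D2 population -> tree node name (None when omitted)
    label_map: dict[str, str | None] = field(default_factory=dict)
    consumed_entries: int = 0
    strict_zeroed: int = 0
    unresolved_entries: int = 0
    initial_nonzero: int = 0


class _Updater:
    def __init__(self, tree: ClassificationTree, X: pd.DataFrame, rejected):
        self.tree = tree
        self.rows = list(X.index)
        self.cols = list(X.columns)
        self.M = X.to_numpy().astype(int).copy()
        self.rejected = dict(rejected) if rejected is not None else {}
        self.report = UpdateReport(initial_nonzero=int((self.M != 0).sum()))

    # -------------------------------------------------------------- #

    def _unique_name(self, name: str) -> str:
        if name not in self.tree:
            return name
        k = 2
        while f"{name} ({k})" in self.tree:
            k += 1
        return f"{name} ({k})"

    def _consume(self, cells: list[tuple[int, int]]) -> None:
        for i, j in cells:
            if self.M[i, j] != 0:
                self.report.consumed_entries += 1
                self.M[i, j] = 0

    def _row_nz(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.M[i])

    def _col_nz(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.M[:, j])

    def _log(self, sc: MatchScenario) -> None:
        self.report.scenarios.append(sc)
        logger.info(
            "%s: D1=%s D2=%s %s",
            sc.kind, list(sc.d1_populations), list(sc.d2_populations), sc.action,
        )

    # -------------------------------------------------------------- #
    # scenario applications
    # -------------------------------------------------------------- #

    def _apply_lone(self, i: int, j: int, value: int) -> None:
        """Lone match between D2 population i and D1 node j."""
        d2, d1 = self.rows[i], self.cols[j]
        node = self.tree.node(d1)
        sided = "reciprocal" if value == 2 else "one-sided"
        if node.is_leaf:
            if d2 != d1:
                self.tree.add_synonym(d1, d2)
            self.report.label_map[d2] = d1
            self._log(MatchScenario(
                "perfect", (d1,), (d2,),
                f"{sided} match; node keeps name {d1!r}, synonym {d2!r}",
            ))
        else:
            new = self._unique_name(d2)
            self.tree.add_child(d1, new)
            self.report.label_map[d2] = new
            self._log(MatchScenario(
                "perfect", (d1,), (d2,),
                f"{sided} match with internal node; {new!r} attached as child of {d1!r}",
            ))
        self._consume([(i, j)])

    def _apply_split(self, j: int, rows: np.ndarray) -> None:
        d1 = self.cols[j]
        d2s = [self.rows[i] for i in rows]
        for d2 in d2s:
            new = self._unique_name(d2)
            self.tree.add_child(d1, new)
            self.report.label_map[d2] = new
        self._log(MatchScenario(
            "split", (d1,), tuple(d2s),
            f"{d1!r} split; {d2s} attached as children",
        ))
        self._consume([(i, j) for i in rows])

    def _try_merge(self, i: int, cols: np.ndarray) -> bool:
        d2 = self.rows[i]
        d1s = [self.cols[j] for j in cols]
        # Matched nodes below other matched nodes are absorbed into their
        # ancestors (the new parent goes above the ancestry-maximal set).
        # When a *single* matched ancestor covers all the others, the new
        # population sits between that ancestor and the matched descendants,
        # so the ancestor is peeled off and the rule recurses on the rest.
        current = list(d1s)
        while True:
            maximal = [
                a for a in current
                if not any(b != a and self.tree.is_ancestor(b, a) for b in current)
            ]
            if len(maximal) >= 2:
                break
            rest = [a for a in current if a != maximal[0]]
            if not rest:
                value = int(self.M[i, cols].max())
                self._consume([(i, j) for j in cols])
                self._apply_lone(i, self.cols.index(maximal[0]), value)
                return True
            current = rest
        parents = {id(self.tree.node(a).parent) for a in maximal}
        if len(parents) != 1:
            return False  # not siblings: degrades to complex
        new = self._unique_name(d2)
        self.tree.insert_parent(new, maximal)
        self.report.label_map[d2] = new
        self._log(MatchScenario(
            "merge", tuple(d1s), (d2,),
            f"{new!r} inserted as parent of {maximal}",
        ))
        self._consume([(i, j) for j in cols])
        return True

    # -------------------------------------------------------------- #
    # passes
    # -------------------------------------------------------------- #

    def _pass_perfect(self, min_top: int) -> bool:
        for i in range(len(self.rows)):
            for j in self._row_nz(i):
                if (
                    self.M[i, j] >= min_top
                    and self._row_nz(i).size == 1
                    and self._col_nz(j).size == 1
                ):
                    self._apply_lone(i, int(j), int(self.M[i, j]))
                    return True
        return False

    def _pass_split(self, min_top: int) -> bool:
        for j in range(len(self.cols)):
            rows = self._col_nz(j)
            if rows.size < 2 or self.M[rows, j].max() < min_top:
                continue
            if all(self._row_nz(i).size == 1 for i in rows):
                self._apply_split(j, rows)
                return True
        return False

    def _pass_merge(self, min_top: int) -> bool:
        for i in range(len(self.rows)):
            cols = self._row_nz(i)
            if cols.size < 2 or self.M[i, cols].max() < min_top:
                continue
            if all(self._col_nz(j).size == 1 for j in cols):
                if self._try_merge(i, cols):
                    return True
        return False

    def _sweep(self, min_top: int) -> None:
        changed = True
        while changed:
            changed = (
                self._pass_perfect(min_top)
                or self._pass_split(min_top)
                or self._pass_merge(min_top)
            )

    def _new_populations(self, initially_empty: set[int]) -> None:
        for i in sorted(initially_empty):
            d2 = self.rows[i]
            if self.rejected.get(d2, False):
                new = self._unique_name(d2)
                self.tree.add_child(self.tree.root.name, new)
                self.report.label_map[d2] = new
                self._log(MatchScenario(
                    "new_population", (), (d2,),
                    f"{new!r} attached as child of the root",
                ))
            else:
                self.report.label_map[d2] = None
                self._log(MatchScenario(
                    "unmatched", (), (d2,),
                    "no match and no reciprocal rejection; population omitted",
                ))

    def _make_strict(self) -> None:
        ones = np.argwhere(self.M == 1)
        for i, j in ones:
            if self._row_nz(i).size > 1 or self._col_nz(j).size > 1:
                self.M[i, j] = 0
                self.report.strict_zeroed += 1

    def run(self) -> UpdateReport:
        initially_empty = {
            i for i in range(len(self.rows)) if self._row_nz(i).size == 0
        }
        self._sweep(min_top=2)
        self._new_populations(initially_empty)
        if (self.M != 0).any():
            self._make_strict()
            self._sweep(min_top=1)
        # whatever remains is complex: omit the involved D2 populations
        for i in range(len(self.rows)):
            cols = self._row_nz(i)
            if cols.size == 0:
                continue
            d2 = self.rows[i]
            d1s = tuple(self.cols[j] for j in cols)
            self.report.unresolved_entries += int(cols.size)
            self.report.label_map.setdefault(d2, None)
            self._log(MatchScenario(
                "complex", d1s, (d2,),
                "could not be added to the tree due to a complex scenario",
            ))
            logger.warning(
                "population %r could not be added to the tree (complex scenario)", d2
            )
            self.M[i] = 0
        # D2 populations never mentioned anywhere keep no mapping entry
        self.tree.validate()
        return self.report


def update_tree(
    tree: ClassificationTree,
    X: pd.DataFrame,
    rejected=None,
) -> tuple[ClassificationTree, UpdateReport]:
    """Apply the matching matrix ``X`` to a copy of ``tree``.

    Parameters
    ----------
    tree : ClassificationTree
        Incumbent tree (D1 side); not modified.
    X : DataFrame
        Matching matrix, rows D2 populations, columns D1 populations
        (a subset of the tree's non-root names), entries in {0, 1, 2}.
    rejected : mapping or Series, optional
        Per D2 population, whether its cells were matched to rejection by the
        incumbent classifier (drives new-population detection).

    Returns
    -------
    (updated tree, UpdateReport)
    """
    X = pd.DataFrame(X)
    bad = [c for c in X.columns if c not in tree or c == tree.root.name]
    if bad:
        raise ValueError(f"matching-matrix columns not in the tree: {bad}")
    if not X.isin([0, 1, 2]).all().all():
        raise ValueError("matching matrix entries must be 0, 1 or 2")
    updater = _Updater(tree.copy(), X, rejected)
    report = updater.run()
    return updater.tree, report


def resolve_scenarios(
    X: pd.DataFrame,
    tree: ClassificationTree | None = None,
    rejected=None,
) -> list[MatchScenario]:
    """Classify the matching matrix into an ordered list of scenarios.

    Without a tree, a flat incumbent tree over the matrix columns is assumed.
    """
    if tree is None:
        tree = ClassificationTree.flat(list(pd.DataFrame(X).columns))
    _, report = update_tree(tree, X, rejected)
    return report.scenarios


def update_from_match(
    tree: ClassificationTree, match: MatchResult
) -> tuple[ClassificationTree, UpdateReport]:
    """Update a tree directly from a :class:`~celltree.matching.MatchResult`."""
    return update_tree(tree, match.X, match.rejected_d2)
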