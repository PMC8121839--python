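"""Matching-matrix scenario resolution and tree edits."""

import numpy as np
import pandas as pd
import pytest

from celltree.tree import parse_tree
from celltree.update import resolve_scenarios, update_tree


def X_of(rows, cols, data):
    return pd.DataFrame(np.asarray(data, dtype=int), index=rows, columns=cols)


class TestPerfect:
    def test_two_perfect_matches(self):
        tree = parse_tree("(a,b)root;")
        X = X_of(["u", "v"], ["a", "b"], [[2, 0], [0, 2]])
        updated, report = update_tree(tree, X)
        assert [s.kind for s in report.scenarios] == ["perfect", "perfect"]
        assert updated == tree  # topology unchanged
        assert updated.name_set("a") == {"a", "u"}
        assert report.label_map == {"u": "a", "v": "b"}

    def test_same_name_no_synonym_needed(self):
        tree = parse_tree("(a,b)root;")
        X = X_of(["a", "b"], ["a", "b"], [[2, 0], [0, 2]])
        updated, report = update_tree(tree, X)
        assert updated.synonyms == {}
        assert report.label_map == {"a": "a", "b": "b"}

    def test_lone_match_with_internal_node_attaches_child(self):
        tree = parse_tree("((a1,a2)a,b)root;")
        X = X_of(["u"], ["a", "a1", "a2", "b"], [[2, 0, 0, 0]])
        updated, report = update_tree(tree, X)
        assert updated.ancestors("u") == ["a"]
        assert report.label_map["u"] == "u"


class TestSplit:
    def test_higher_resolution_attaches_children(self):
        tree = parse_tree("(p,q)root;")
        X = X_of(["u", "v", "q"], ["p", "q"], [[2, 0], [2, 0], [0, 2]])
        updated, report = update_tree(tree, X)
        kinds = [s.kind for s in report.scenarios]
        assert "split" in kinds
        assert sorted(c.name for c in updated.node("p").children) == ["u", "v"]

    def test_split_accepts_one_sided_member(self):
        """A 2 plus a 1 in the same column still split (uneven fractions can
        drop one direction below the binarisation threshold)."""
        tree = parse_tree("(p,q)root;")
        X = X_of(["u", "v", "q"], ["p", "q"], [[2, 0], [1, 0], [0, 2]])
        updated, report = update_tree(tree, X)
        assert sorted(c.name for c in updated.node("p").children) == ["u", "v"]


class TestMerge:
    def test_lower_resolution_inserts_parent(self):
        tree = parse_tree("(a,b,c)root;")
        X = X_of(["m", "c"], ["a", "b", "c"], [[2, 2, 0], [0, 0, 2]])
        updated, report = update_tree(tree, X)
        assert {c.name for c in updated.node("m").children} == {"a", "b"}
        assert updated.ancestors("a") == ["m"]

    def test_merge_with_matched_ancestor_goes_below_it(self):
        """When the matched set contains a node's own ancestor, the new
        population is inserted between the ancestor and the matched leaves."""
        tree = parse_tree("((g4,g5,g6)g456,g1)root;")
        X = X_of(
            ["m", "g1"],
            ["g456", "g4", "g5", "g6", "g1"],
            [[1, 0, 2, 2, 0], [0, 0, 0, 0, 2]],
        )
        updated, report = update_tree(tree, X)
        assert {c.name for c in updated.node("m").children} == {"g5", "g6"}
        assert updated.ancestors("m") == ["g456"]

    def test_merge_absorbs_matched_descendants(self):
        tree = parse_tree("(a,(b1,b2)b)root;")
        X = X_of(["m"], ["a", "b", "b1", "b2"], [[2, 2, 1, 1]])
        updated, report = update_tree(tree, X)
        assert {c.name for c in updated.node("m").children} == {"a", "b"}

    def test_non_sibling_merge_degrades_to_complex(self):
        tree = parse_tree("((a)p,b)root;")
        X = X_of(["m"], ["a", "b"], [[2, 2]])
        updated, report = update_tree(tree, X)
        assert [s.kind for s in report.scenarios] == ["complex"]
        assert report.label_map["m"] is None
        assert updated == tree


class TestNewPopulation:
    def test_reciprocal_rejection_attaches_to_root(self):
        tree = parse_tree("(a,b)root;")
        X = X_of(["a", "b", "n"], ["a", "b"], [[2, 0], [0, 2], [0, 0]])
        updated, report = update_tree(tree, X, rejected={"n": True})
        assert updated.node("n").parent is updated.root
        assert [s.kind for s in report.scenarios][-1] == "new_population"

    def test_unmatched_without_rejection_is_omitted(self):
        tree = parse_tree("(a,b)root;")
        X = X_of(["n"], ["a", "b"], [[0, 0]])
        updated, report = update_tree(tree, X)
        assert "n" not in updated
        assert report.scenarios[0].kind == "unmatched"
        assert report.label_map["n"] is None


class TestStrictPass:
    def test_stray_one_sided_entries_cleared_then_resolved(self):
        """A reciprocal diagonal obscured by one-sided noise resolves after
        the strict pass."""
        tree = parse_tree("(a,b,c)root;")
        X = X_of(
            ["u", "v", "w"],
            ["a", "b", "c"],
            [[2, 1, 0], [1, 2, 0], [0, 1, 2]],
        )
        updated, report = update_tree(tree, X)
        assert report.label_map == {"u": "a", "v": "b", "w": "c"}
        assert report.strict_zeroed == 3
        assert updated == tree

    def test_isolated_one_sided_match_survives_strict(self):
        tree = parse_tree("(a,b,c)root;")
        X = X_of(
            ["u", "v", "w"],
            ["a", "b", "c"],
            [[2, 1, 0], [1, 2, 0], [0, 0, 1]],
        )
        updated, report = update_tree(tree, X)
        # w--c is the sole nonzero of its row and column: kept and applied
        assert report.label_map["w"] == "c"


class TestBookkeeping:
    def test_all_zero_matrix_means_no_change(self):
        tree = parse_tree("(a,b)root;")
        X = X_of([], ["a", "b"], np.zeros((0, 2)))
        updated, report = update_tree(tree, X)
        assert updated == tree
        assert report.scenarios == []

    def test_entry_accounting(self):
        tree = parse_tree("(a,b,c)root;")
        X = X_of(
            ["u", "v", "w"],
            ["a", "b", "c"],
            [[2, 1, 0], [1, 2, 0], [0, 1, 2]],
        )
        _, report = update_tree(tree, X)
        total = (
            report.consumed_entries
            + report.strict_zeroed
            + report.unresolved_entries
        )
        assert total == report.initial_nonzero == 6

    def test_invalid_entries_rejected(self):
        tree = parse_tree("(a,b)root;")
        with pytest.raises(ValueError):
            update_tree(tree, X_of(["u"], ["a", "b"], [[3, 0]]))

    def test_unknown_column_rejected(self):
        tree = parse_tree("(a,b)root;")
        with pytest.raises(ValueError, match="zzz"):
            update_tree(tree, X_of(["u"], ["zzz"], [[1]]))

    def test_tree_validity_after_every_figure_scenario(self):
        """Perfect, split, merge and new-population edits all preserve the
        unique-name and single-root invariants."""
        tree = parse_tree("(a,b,c,d)root;")
        X = X_of(
            ["syn", "s1", "s2", "m", "n"],
            ["a", "b", "c", "d"],
            [
                [2, 0, 0, 0],  # perfect with a
                [0, 2, 0, 0],  # split of b ...
                [0, 2, 0, 0],  # ... into s1, s2
                [0, 0, 2, 2],  # merge of c, d
                [0, 0, 0, 0],  # new population
            ],
        )
        updated, report = update_tree(tree, X, rejected={"n": True})
        updated.validate()
        kinds = sorted(s.kind for s in report.scenarios)
        assert kinds == ["merge", "new_population", "perfect", "split"]

    def test_name_collision_disambiguated(self):
        tree = parse_tree("((x)p,q)root;")
        # D2 population also called "q" splits p: attached under a new name
        X = X_of(["q", "x"], ["p", "x", "q"], [[2, 0, 0], [0, 2, 0]])
        updated, report = update_tree(tree, X)
        updated.validate()
        assert report.label_map["q"] not in ("q",)  # renamed on attach


class TestResolveScenarios:
    def test_flat_default_tree(self):
        X = X_of(["u", "v"], ["a", "b"], [[2, 0], [0, 2]])
        kinds = [s.kind for s in resolve_scenarios(X)]
        assert kinds == ["perfect", "perfect"]
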