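"""Confusion matrices, row normalisation, binarisation and the matching matrix."""

import itertools

import numpy as np
import pandas as pd
import pytest

from celltree.classifier import train_hierarchy
from celltree.matching import (
    binarize_matches,
    build_matching_matrix,
    cross_prediction_confusion,
    match_labels,
    normalize_confusion,
)


class TestConfusion:
    def test_perfect_self_prediction_diagonal(self):
        y = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        C = cross_prediction_confusion(y, y, ["a", "b", "c"])
        assert np.array_equal(np.diag(C.loc[["a", "b", "c"], ["a", "b", "c"]]),
                              [10, 10, 10])

    def test_all_rejected_single_column(self):
        C = cross_prediction_confusion(
            ["a", "a", "b"], ["rejected"] * 3, ["x", "y"]
        )
        assert C["rejected"].sum() == 3
        assert C.drop(columns="rejected").to_numpy().sum() == 0

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["a", "b", "c"], 100)
        p = rng.choice(["x", "y", "rejected"], 100)
        C = cross_prediction_confusion(y, p, ["x", "y"])
        assert C.to_numpy().sum() == 100

    def test_unknown_prediction_error(self):
        with pytest.raises(ValueError, match="zzz"):
            cross_prediction_confusion(["a"], ["zzz"], ["x"])


class TestNormalize:
    def test_row_fraction_arithmetic(self):
        C = pd.DataFrame([[30, 10, 0]], index=["p"], columns=list("xyz"))
        NC = normalize_confusion(C)
        assert np.allclose(NC.loc["p"], [0.75, 0.25, 0.0])

    def test_idempotent_on_stochastic_rows(self):
        NC = pd.DataFrame([[0.5, 0.5], [1.0, 0.0]], columns=["x", "y"])
        assert np.allclose(normalize_confusion(NC), NC)

    def test_zero_row_error(self):
        C = pd.DataFrame([[1, 0], [0, 0]], index=["a", "b"], columns=["x", "y"])
        with pytest.raises(ValueError, match="b"):
            normalize_confusion(C)


def binarize_oracle_row(vals, threshold):
    """Independent restatement of the ranking rule: keep the top fraction and
    every following nonzero fraction while consecutive ranked gaps stay below
    the threshold."""
    order = np.argsort(-np.asarray(vals), kind="stable")
    out = np.zeros(len(vals), dtype=int)
    ranked = [vals[j] for j in order]
    keep = 0
    for k, v in enumerate(ranked):
        if v <= 0:
            break
        if k > 0 and ranked[k - 1] - v >= threshold:
            break
        keep = k + 1
    out[order[:keep]] = 1
    return out


class TestBinarize:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([0.9, 0.1, 0.0], [1, 0, 0]),
            ([0.5, 0.45, 0.05], [1, 1, 0]),
            ([0.5, 0.5, 0.0], [1, 1, 0]),
            ([1 / 3, 1 / 3, 1 / 3], [1, 1, 1]),
        ],
    )
    def test_rule_examples(self, row, expected):
        NC = pd.DataFrame([row], columns=list("abc"))
        assert binarize_matches(NC, 0.25).loc[0].tolist() == expected

    def test_exhaustive_three_column_grid(self):
        """All 3-column stochastic rows on a 0.05 grid match the oracle."""
        grid = np.arange(0, 21)
        rows = [
            np.array([a, b, 20 - a - b]) / 20.0
            for a, b in itertools.product(grid, grid)
            if a + b <= 20
        ]
        NC = pd.DataFrame(rows, columns=list("abc"))
        for threshold in (0.1, 0.25, 0.5):
            BC = binarize_matches(NC, threshold).to_numpy()
            expected = np.array(
                [binarize_oracle_row(list(r), threshold) for r in rows]
            )
            assert np.array_equal(BC, expected)

    def test_robust_rows_invariant_across_thresholds(self):
        """Rows whose top gap exceeds the largest threshold keep the same
        binarisation across the whole threshold grid."""
        NC = pd.DataFrame([[0.8, 0.2, 0.0], [0.7, 0.15, 0.15]])
        results = [binarize_matches(NC, t).to_numpy() for t in (0.1, 0.25, 0.5)]
        assert all(np.array_equal(results[0], r) for r in results)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            binarize_matches(pd.DataFrame([[1.0]]), 0.0)


class TestMatchingMatrix:
    def test_reciprocal_identity(self):
        pops = ["a", "b", "c"]
        I = pd.DataFrame(np.eye(3, dtype=int), index=pops, columns=pops)
        X = build_matching_matrix(I, I, pops, pops)
        assert np.array_equal(X.to_numpy(), 2 * np.eye(3, dtype=int))

    def test_one_sided_entries_are_one(self):
        pops = ["a", "b"]
        BC1 = pd.DataFrame([[1, 1], [0, 1]], index=pops, columns=pops)
        BC2 = pd.DataFrame(0, index=pops, columns=pops)
        X = build_matching_matrix(BC1, BC2, pops, pops)
        assert set(X.to_numpy().ravel()) <= {0, 1}
        assert X.to_numpy().sum() == 3

    def test_role_swap_transposes(self):
        rng = np.random.default_rng(1)
        pops1, pops2 = ["a", "b", "c"], ["u", "v"]
        BC1 = pd.DataFrame(rng.integers(0, 2, (3, 2)), index=pops1, columns=pops2)
        BC2 = pd.DataFrame(rng.integers(0, 2, (2, 3)), index=pops2, columns=pops1)
        X12 = build_matching_matrix(BC1, BC2, pops1, pops2)
        X21 = build_matching_matrix(BC2, BC1, pops2, pops1)
        assert np.array_equal(X12.to_numpy(), X21.to_numpy().T)

    def test_shape_mismatch(self):
        BC1 = pd.DataFrame([[1]], index=["a"], columns=["u"])
        BC2 = pd.DataFrame([[1]], index=["u"], columns=["b"])
        with pytest.raises(ValueError):
            build_matching_matrix(BC1, BC2, ["a"], ["u"])


class TestSelfMatch:
    def test_split_halves_give_two_i(self, small_sim):
        """A well-separated dataset matched against its own other half is a
        perfect diagonal of reciprocal matches."""
        ds, _ = small_sim
        rng = np.random.default_rng(0)
        idx = rng.permutation(ds.X.shape[0])
        half = len(idx) // 2
        i1, i2 = idx[:half], idx[half:]
        h1 = train_hierarchy(ds.X[i1], ds.labels[i1], None, n_components=50)
        h2 = train_hierarchy(ds.X[i2], ds.labels[i2], None, n_components=50)
        res = match_labels(h1, h2, ds.X[i1], ds.labels[i1], ds.X[i2], ds.labels[i2])
        pops = sorted(set(ds.labels))
        X = res.X.loc[pops, pops].to_numpy()
        assert np.array_equal(X, 2 * np.eye(len(pops), dtype=int))
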