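"""Thresholded-NCA selection: normalisation, elimination, weights, ranking."""

import warnings

import numpy as np
import pytest

from eegmotif.nca import (
    NCAParams,
    SelectionResult,
    eliminate_by_threshold,
    minmax_normalize,
    nca_objective,
    nca_weights,
    select_features,
    select_top_k,
)


class TestMinMax:
    def test_affine_endpoints(self):
        out = minmax_normalize(np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(out[:, 0], [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        out = minmax_normalize(np.array([[7.0, 1.0], [7.0, 2.0], [7.0, 3.0]]))
        np.testing.assert_array_equal(out[:, 0], 0)

    def test_output_contract(self, rng):
        out = minmax_normalize(rng.normal(size=(20, 8)) * 100)
        np.testing.assert_allclose(out.min(axis=0), 0, atol=1e-15)
        assert np.all((np.abs(out.max(axis=0) - 1) < 1e-15) | (out.max(axis=0) == 0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize(np.empty((0, 3)))


class TestElimination:
    def test_zero_sum_column_removed(self):
        XN = np.array([[0.0, 0.5, 1.0], [0.0, 1.0, 0.2]])
        kept, idx = eliminate_by_threshold(XN)
        assert idx.tolist() == [1, 2]
        assert kept.shape == (2, 2)

    def test_nothing_removed_when_all_positive(self, rng):
        XN = rng.uniform(0.1, 1.0, size=(5, 4))
        kept, idx = eliminate_by_threshold(XN)
        assert idx.tolist() == [0, 1, 2, 3]

    def test_infinite_threshold_warns_and_empties(self, rng):
        with pytest.warns(UserWarning, match="eliminated every feature"):
            _, idx = eliminate_by_threshold(rng.uniform(size=(4, 3)), th=np.inf)
        assert idx.size == 0

    def test_removes_exactly_constant_raw_columns(self, rng):
        X = rng.normal(size=(10, 6))
        X[:, 2] = 4.2
        X[:, 5] = -1.0
        _, idx = eliminate_by_threshold(minmax_normalize(X))
        assert idx.tolist() == [0, 1, 3, 4]


def _auto_sigma(X):
    """Same bandwidth rule the optimiser applies at the all-ones weights."""
    D = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    off = D[~np.eye(len(X), dtype=bool)]
    return float(off.std())


class TestWeights:
    def test_informative_feature_beats_noise_and_matches_grid_oracle(self):
        rng = np.random.default_rng(42)
        n = 100
        y = np.repeat([1, 2], n // 2)
        X = np.column_stack(
            [np.where(y == 1, 0.0, 1.0) + 0.05 * rng.normal(size=n), rng.uniform(size=n)]
        )
        w = nca_weights(X, y)
        assert w[0] > 2 * w[1]
        # independent oracle: exhaustive grid over the same objective
        sigma, lam = _auto_sigma(X), 1.0 / n**2
        grid = np.linspace(0, 3, 31)
        scores = {
            (a, b): nca_objective(X, y, np.array([a, b]), sigma, lam)
            for a in grid
            for b in grid
        }
        (a_best, b_best) = max(scores, key=scores.get)
        assert a_best > 2 * b_best
        # the optimiser should be near the grid optimum's objective value
        assert nca_objective(X, y, w, sigma, lam) >= scores[(a_best, b_best)] - 1e-3

    def test_objective_not_worse_than_start(self, rng):
        X = rng.normal(size=(40, 10))
        y = np.array([1, 2] * 20)
        X[:, 0] += (y == 2) * 3.0
        w = nca_weights(X, y)
        sigma, lam = _auto_sigma(X), 1.0 / 40**2
        assert nca_objective(X, y, w, sigma, lam) >= nca_objective(
            X, y, np.ones(10), sigma, lam
        )

    def test_duplicated_columns_get_equal_weights(self, rng):
        base = rng.normal(size=(60, 1))
        y = np.array([1, 2] * 30)
        X = np.hstack([base, base, rng.normal(size=(60, 1))])
        w = nca_weights(X, y)
        assert abs(w[0] - w[1]) < 1e-6

    def test_huge_regularisation_shrinks_all_weights(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.array([1, 2] * 15)
        w = nca_weights(X, y, NCAParams(lam=50.0))
        assert np.all(w < 0.1)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            nca_weights(rng.normal(size=(10, 3)), np.ones(10))

    def test_streaming_engine_matches_precomputed(self, rng):
        X = rng.normal(size=(25, 40))
        y = np.array([1, 2] * 12 + [1])
        X[:, 3] += (y == 2) * 2.0
        w_pre = nca_weights(X, y)
        w_stream = nca_weights(X, y, NCAParams(memory_budget_bytes=0))
        np.testing.assert_allclose(w_pre, w_stream, rtol=1e-4, atol=1e-6)


class TestTopK:
    def test_ranking_contract(self):
        res = select_top_k(np.array([0.9, 0.1, 0.5]), np.array([10, 11, 12]), k=2)
        assert res.ranked_indices.tolist() == [10, 12, 11]
        assert res.selected_indices.tolist() == [10, 12]

    def test_saturation_warns(self):
        with pytest.warns(UserWarning, match="keeping all"):
            res = select_top_k(np.array([0.3, 0.2]), np.array([0, 1]), k=5)
        assert res.selected_indices.tolist() == [0, 1]

    def test_ties_break_by_lower_original_index(self):
        res = select_top_k(np.array([0.5, 0.5, 0.5]), np.array([7, 3, 5]), k=2)
        assert res.selected_indices.tolist() == [3, 5]

    def test_json_roundtrip(self, tmp_path):
        res = select_top_k(np.array([0.9, 0.1]), np.array([4, 2]), k=1)
        res.to_json(tmp_path / "sel.json")
        back = SelectionResult.from_json(tmp_path / "sel.json")
        np.testing.assert_array_equal(back.selected_indices, res.selected_indices)
        np.testing.assert_array_equal(back.weights, res.weights)


class TestEndToEndSelection:
    def test_planted_features_recovered_small(self):
        rng = np.random.default_rng(5)
        n, d, n_inf = 100, 400, 10
        y = np.repeat([1, 2], n // 2)
        X = rng.normal(size=(n, d))
        X[y == 2, :n_inf] += 2.0
        sel = select_features(X, y, k=40)
        hits = len(set(range(n_inf)) & set(sel.selected_indices.tolist()))
        assert hits >= 8
        assert set(sel.selected_indices) <= set(sel.ranked_indices)
        assert set(sel.ranked_indices) == set(sel.surviving_indices)
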