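"""Feature selection, redundancy pruning, normal-equation MLR, evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import fatiguekit as fk
from fatiguekit.modeling import (FeatureMatrix, SelectionResult, drop_redundant,
                                 evaluate_grid, fatigue_class_of_score, fit_mlr,
                                 pearson_r_p, rmse, select_features)
from conftest import exactly_linear_matrix


def _matrix(X, fas):
    X = pd.DataFrame(X)
    X.columns = [f"np_f{i}_C3" for i in range(X.shape[1])]
    X.index = [f"S{i}" for i in range(len(X))]
    return FeatureMatrix(X=X, fas=pd.Series(np.asarray(fas, float), index=X.index))


class TestAssemble:
    def test_incomplete_subjects_excluded(self):
        rng = np.random.default_rng(1)
        rows = {f"S{i}": {"a": float(rng.normal()), "b": 1.0} for i in range(17)}
        for sid in ("S3", "S8", "S12"):
            rows[sid] = None
        fas = {f"S{i}": 20.0 + i for i in range(17)}
        fm = fk.assemble_feature_matrix(rows, fas)
        assert fm.m == 14
        assert "S03" not in fm.X.index

    def test_column_mismatch_and_duplicates_rejected(self):
        rows = {"S0": {"a": 1.0}, "S1": {"b": 1.0}, "S2": {"a": 1.0}}
        with pytest.raises(ValueError, match="feature names"):
            fk.assemble_feature_matrix(rows, {s: 20.0 for s in rows})
        X = pd.DataFrame(np.ones((3, 2)), columns=["a", "a"],
                         index=["S0", "S1", "S2"])
        with pytest.raises(ValueError, match="duplicate"):
            FeatureMatrix(X=X, fas=pd.Series([20.0, 21.0, 22.0], index=X.index))

    def test_full_pipeline_column_budget(self, noiseless_matrix):
        assert noiseless_matrix.X.shape == (14, 226)


class TestSelection:
    def test_planted_feature_ranked_first(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((14, 20))
        fas = 30.0 + 5.0 * X[:, 7]
        sel = select_features(_matrix(X, fas))
        assert sel.table.iloc[0]["feature"] == "np_f7_C3"
        assert sel.table.iloc[0]["p"] < 1e-6
        assert sel.K == len(sel.table)

    def test_r_p_match_closed_form_and_scipy(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((12, 30))
        y = rng.standard_normal(12)
        r, p = pearson_r_p(X, y)
        for j in range(30):
            r_ref, p_ref = stats.pearsonr(X[:, j], y)
            assert r[j] == pytest.approx(r_ref, abs=1e-10)
            assert p[j] == pytest.approx(p_ref, abs=1e-10)
            t = r[j] * np.sqrt((12 - 2) / (1 - r[j] ** 2))
            assert p[j] == pytest.approx(2 * stats.t.sf(abs(t), 10), abs=1e-12)

    def test_zero_variance_column_assigned_p_one(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((10, 3))
        X[:, 1] = 4.2
        r, p = pearson_r_p(X, rng.standard_normal(10))
        assert r[1] == 0.0 and p[1] == 1.0
        sel = select_features(_matrix(X, np.arange(10.0)))
        assert "np_f1_C3" not in sel.features

    def test_type_one_error_calibrated(self):
        """Pure-noise selection at m=14 keeps ~5% of features at alpha=0.05."""
        rng = np.random.default_rng(6)
        hits = total = 0
        for _ in range(1000):
            X = rng.standard_normal((14, 50))
            _, p = pearson_r_p(X, rng.standard_normal(14))
            hits += int((p < 0.05).sum())
            total += 50
        assert hits / total == pytest.approx(0.05, abs=0.02)

    def test_deterministic_tie_break(self):
        X = np.zeros((6, 2))
        X[:, 0] = [1, 2, 3, 4, 5, 6]
        X[:, 1] = [6, 5, 4, 3, 2, 1]
        sel = select_features(_matrix(X, [1, 2, 3, 4, 5, 6.0]))
        assert sel.features == ["np_f0_C3", "np_f1_C3"]  # equal p -> name order


class TestDropRedundant:
    def _sel(self, rows):
        table = pd.DataFrame(rows, columns=["feature", "r", "p"])
        table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
        return SelectionResult(table=table, alpha=0.05)

    def test_reciprocal_pair_keeps_lower_p(self):
        sel = self._sel([("ratio_alpha_theta_O2", -0.78, 0.0011),
                         ("ratio_theta_alpha_O2", 0.78, 0.0011),
                         ("ratio_beta_theta_C3", -0.83, 0.0003)])
        out = drop_redundant(sel)
        assert "ratio_alpha_theta_O2" in out.features
        assert "ratio_theta_alpha_O2" not in out.features
        assert "ratio_beta_theta_C3" in out.features

    def test_no_reciprocal_pairs_noop(self):
        sel = self._sel([("ratio_beta_theta_C3", -0.8, 0.001),
                         ("p300_lat_C3", 0.59, 0.027),
                         ("ratio_beta_theta_O2", -0.65, 0.011)])
        assert drop_redundant(sel).features == sel.features

    def test_different_channels_not_paired(self):
        sel = self._sel([("ratio_alpha_theta_O2", -0.7, 0.001),
                         ("ratio_theta_alpha_C3", 0.6, 0.02)])
        assert len(drop_redundant(sel).features) == 2

    @given(st.lists(st.tuples(st.sampled_from(["alpha", "theta", "beta"]),
                              st.sampled_from(["alpha", "theta", "beta"]),
                              st.sampled_from(["C3", "O2"])),
                    min_size=0, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_output_never_contains_both_members(self, triples):
        rng = np.random.default_rng(7)
        rows = []
        seen = set()
        for b1, b2, ch in triples:
            if b1 == b2:
                continue
            name = f"ratio_{b1}_{b2}_{ch}"
            if name in seen:
                continue
            seen.add(name)
            rows.append((name, 0.5, float(rng.uniform(0.0001, 0.049))))
        if not rows:
            return
        out = drop_redundant(self._sel(rows))
        names = set(out.features)
        for name in names:
            b1, b2, ch = name.split("_")[1:]
            assert f"ratio_{b2}_{b1}_{ch}" not in names


class TestFitMLR:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((12, 3))
        w_true = np.array([2.0, -1.5, 0.5])
        y = 7.0 + X @ w_true
        model = fit_mlr(X, y)
        np.testing.assert_allclose(model.weights, np.r_[7.0, w_true], atol=1e-9)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-9)

    def test_intercept_only_is_mean(self):
        y = np.array([18.0, 25.0, 31.0, 40.0])
        model = fit_mlr(np.empty((4, 0)), y)
        assert model.weights[0] == pytest.approx(y.mean())

    def test_matches_qr_least_squares_oracle(self):
        rng = np.random.default_rng(9)
        from scipy.linalg import lstsq

        for _ in range(20):
            X = rng.standard_normal((15, 4))
            y = rng.standard_normal(15)
            model = fit_mlr(X, y)
            X1 = np.column_stack([np.ones(15), X])
            ref, *_ = lstsq(X1, y, lapack_driver="gelsy")
            np.testing.assert_allclose(model.weights, ref, atol=1e-8)

    def test_rank_deficient_uses_minimum_norm(self, caplog):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((4, 6))  # n < k + 1, reachable under LOO
        y = rng.standard_normal(4)
        with caplog.at_level("WARNING", logger="fatiguekit.modeling"):
            model = fit_mlr(X, y)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)


class TestRMSE:
    def test_hand_arithmetic_and_identity(self):
        assert rmse([20.0, 30.0], [22.0, 28.0]) == pytest.approx(2.0)
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(11)
        y, yhat = rng.standard_normal((2, 100))
        assert rmse(y, yhat) == pytest.approx(
            np.sqrt(np.mean((y - yhat) ** 2)), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestEvaluateGrid:
    def test_perfect_linear_matrix_recovered_at_all_durations(self):
        fm = exactly_linear_matrix(m=14, k=3, seed=12)
        grid = evaluate_grid({d: fm for d in (240.0, 120.0, 60.0, 30.0, 15.0)},
                             variant="EEG", splits=("70:30",), k_max=3,
                             repeats=5, seed=1)
        cells = grid.table[grid.table.k == 3]
        assert len(cells) == 5
        assert (cells.accuracy_mean == 100.0).all()
        assert (cells.rmse_mean < 1e-6).all()

    def test_same_seed_reproduces_grid(self):
        fm = exactly_linear_matrix(m=10, k=2, seed=13, noise_sd=3.0)
        a = evaluate_grid(fm, splits=("70:30", "LOO"), k_max=4, repeats=5, seed=3)
        b = evaluate_grid(fm, splits=("70:30", "LOO"), k_max=4, repeats=5, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)
        c = evaluate_grid(fm, splits=("70:30", "LOO"), k_max=4, repeats=5, seed=4)
        assert not a.table.equals(c.table)

    def test_split_sizes_match_protocol(self):
        from fatiguekit.modeling import _test_size

        assert _test_size("70:30", 14) == 4  # 10 train / 4 test
        assert _test_size("80:20", 14) == 3  # 11 train / 3 test
        assert _test_size("LOO", 14) == 1

    def test_selection_ignores_test_subjects(self):
        """Leakage guard: perturbing a held-out subject's features must not
        change the training-fold selection."""
        fm = exactly_linear_matrix(m=12, k=2, seed=14, noise_sd=2.0)
        rng = np.random.default_rng(0)
        test_idx = np.array([2, 5, 9])
        train_mask = np.ones(12, bool)
        train_mask[test_idx] = False
        train = FeatureMatrix(X=fm.X.iloc[train_mask], fas=fm.fas.iloc[train_mask])
        sel_before = select_features(train).features
        X_perturbed = fm.X.copy()
        X_perturbed.iloc[2] = rng.standard_normal(fm.X.shape[1]) * 100
        train_after = FeatureMatrix(X=X_perturbed.iloc[train_mask],
                                    fas=fm.fas.iloc[train_mask])
        assert select_features(train_after).features == sel_before

    def test_unavailable_cells_are_nan(self):
        # only 3 informative columns exist; demand k up to 12
        fm = exactly_linear_matrix(m=14, k=3, seed=15)
        grid = evaluate_grid(fm, variant="EEG", splits=("70:30",), k_max=12,
                             repeats=3, seed=5)
        cell = grid.table[grid.table.k == 12].iloc[0]
        assert cell.n_repeats_available < 3

    def test_class_binning_of_predictions(self):
        assert fatigue_class_of_score(21.4) == "no_fatigue"
        assert fatigue_class_of_score(21.6) == "substantial"
        assert fatigue_class_of_score(35.4) == "substantial"
        assert fatigue_class_of_score(35.6) == "extreme"
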