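"""Stability selection, nested CV, permutation test, biomarker ranking."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from mucopred import model
from oracles import auc_pairs, soft_threshold

TINY_GRID = ({"n_estimators": 30, "max_features": "sqrt",
              "min_samples_leaf": 1},)


def standardized(rng, n, p):
    x = rng.normal(size=(n, p))
    return (x - x.mean(0)) / x.std(0)


class TestLasso:
    def test_large_penalty_shrinks_single_feature_to_zero(self, rng):
        x = standardized(rng, 30, 1)
        y = 0.3 * x[:, 0] + rng.normal(size=30)
        cov = abs((x[:, 0] * (y - y.mean())).mean())
        coefs = model.lasso_fit(x, y, penalty=cov + 0.01)
        assert coefs[0] == 0.0

    def test_penalty_to_zero_approaches_ols(self, rng):
        for _ in range(20):
            x = standardized(rng, 40, 3)
            y = x @ np.array([1.0, -0.5, 0.2]) + rng.normal(scale=0.1, size=40)
            coefs = model.lasso_fit(x, y, penalty=1e-8)
            ols = np.linalg.lstsq(
                np.column_stack([np.ones(40), x]), y, rcond=None)[0][1:]
            assert np.abs(coefs - ols).max() < 1e-4

    def test_orthonormal_design_soft_threshold_identity(self, rng):
        # columns orthogonal with X'X = nI: each coefficient is the
        # soft-thresholded univariate OLS estimate.
        for _ in range(20):
            n = 32
            q, _ = np.linalg.qr(rng.normal(size=(n, 4)))
            x = q * np.sqrt(n)  # mean ~0 columns with ||x_j||^2 = n
            x = (x - x.mean(0)) / x.std(0)
            # re-orthogonalise after standardisation
            q, _ = np.linalg.qr(x)
            x = q * np.sqrt(n)
            sd = x.std(0)
            if np.abs(sd - 1).max() > 1e-6:
                continue  # standardisation must be a no-op for the identity
            y = rng.normal(size=n)
            penalty = 0.15
            coefs = model.lasso_fit(x, y, penalty)
            for j in range(4):
                ols_j = x[:, j] @ (y - y.mean()) / n
                assert coefs[j] == pytest.approx(
                    soft_threshold(ols_j, penalty), abs=1e-6)

    def test_constant_column_dropped_with_warning(self, rng):
        x = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="constant"):
            coefs = model.lasso_fit(x, y, penalty=0.01)
        assert coefs[0] == 0.0

    def test_logistic_variant_runs(self, rng):
        x = standardized(rng, 30, 2)
        y = (x[:, 0] > 0).astype(float)
        coefs = model.lasso_fit(x, y, penalty=0.05, logistic=True)
        assert coefs.shape == (2,)
        assert coefs[0] != 0


class TestAuc:
    def test_perfect_and_ties(self):
        assert model.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert model.auc([0.5] * 4, [0, 0, 1, 1]) == 0.5

    def test_pair_enumeration_example(self):
        assert model.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_matches_pair_oracle_and_sklearn(self, rng):
        for _ in range(20):
            scores = rng.choice(np.linspace(0, 1, 7), size=12)
            labels = rng.integers(0, 2, size=12)
            if len(np.unique(labels)) < 2:
                continue
            ours = model.auc(scores, labels)
            assert ours == pytest.approx(auc_pairs(scores, labels), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(labels, scores),
                                         abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            model.auc([0.1, 0.9], [1, 1])


class TestStabilitySelect:
    @staticmethod
    def planted(rng, n=40, p=200):
        y = rng.integers(0, 2, size=n).astype(float)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, size=n).astype(float)
        x = rng.normal(size=(n, p))
        x[:, 0] = y + rng.normal(scale=0.05, size=n)
        cols = [f"ASV_{i + 1:03d}" for i in range(p)]
        return pd.DataFrame(x, columns=cols), y

    def test_planted_feature_attains_max_count(self, rng):
        wins = 0
        for seed in range(10):
            x, y = self.planted(rng)
            res = model.stability_select(x, y, n_splits=15, seed=seed)
            if res.selection_counts["ASV_001"] == res.selection_counts.max():
                wins += 1
        assert wins >= 9

    def test_permuted_labels_lower_max_count(self, rng):
        # the max stability score under permuted labels sits stochastically
        # below the planted-signal case; compare means over paired runs
        signal_max, chance_max = [], []
        for seed in range(5):
            x, y = self.planted(rng)
            signal = model.stability_select(x, y, n_splits=15, seed=seed)
            chance = model.stability_select(x, rng.permutation(y),
                                            n_splits=15, seed=seed)
            signal_max.append(signal.selection_counts.max())
            chance_max.append(chance.selection_counts.max())
        assert np.mean(signal_max) > np.mean(chance_max)

    def test_top_k_saturation_returns_all_selected(self, rng):
        x, y = self.planted(rng, p=20)
        res = model.stability_select(x, y, n_splits=10, top_k=100, seed=1)
        nonzero = res.selection_counts[res.selection_counts > 0]
        assert set(res.selected_features) == set(nonzero.index)
        counts = [res.selection_counts[f] for f in res.selected_features]
        assert counts == sorted(counts, reverse=True)

    def test_column_order_invariance(self, rng):
        x, y = self.planted(rng, p=30)
        a = model.stability_select(x, y, n_splits=10, seed=2)
        b = model.stability_select(x[x.columns[::-1]], y, n_splits=10, seed=2)
        assert a.selected_features == b.selected_features

    def test_single_class_rejected(self, rng):
        x, _ = self.planted(rng, p=5)
        with pytest.raises(ValueError):
            model.stability_select(x, np.ones(len(x)), n_splits=5, seed=0)


class TestNestedCv:
    def test_separable_feature_gives_auc_one(self, rng):
        n = 40
        y = np.repeat([0, 1], n // 2)
        x = pd.DataFrame({"f1": y + rng.normal(scale=0.01, size=n),
                          "f2": rng.normal(size=n)})
        res = model.nested_cv_evaluate(x, y, grid=TINY_GRID, n_outer=5,
                                       seed=0)
        assert res.mean_auc == pytest.approx(1.0)
        assert res.mean_auc == pytest.approx(np.mean(res.outer_split_aucs))

    def test_null_centred_at_half(self, rng):
        # pure-noise X: mean AUC over replicates should sit near 0.5
        means = []
        for seed in range(50):
            local = np.random.default_rng(seed)
            y = np.repeat([0, 1], 20)
            x = pd.DataFrame(local.normal(size=(40, 20)))
            x.columns = [f"f{i}" for i in x.columns]
            res = model.nested_cv_evaluate(x, y, grid=TINY_GRID, n_outer=3,
                                           seed=seed)
            means.append(res.mean_auc)
        assert abs(np.mean(means) - 0.5) < 0.05

    def test_importances_nonnegative_and_aligned(self, rng):
        y = np.repeat([0, 1], 15)
        x = pd.DataFrame(rng.normal(size=(30, 6)),
                         columns=[f"f{i}" for i in range(6)])
        res = model.nested_cv_evaluate(x, y, grid=TINY_GRID, n_outer=3,
                                       seed=1)
        assert (res.mean_feature_importance >= 0).all()
        assert list(res.mean_feature_importance.index) == list(x.columns)

    def test_minority_class_guard(self, rng):
        y = np.array([0] * 18 + [1] * 2)
        x = pd.DataFrame(rng.normal(size=(20, 3)))
        x.columns = ["a", "b", "c"]
        with pytest.raises(ValueError):
            model.nested_cv_evaluate(x, y, grid=TINY_GRID, inner_folds=5,
                                     seed=0)


class TestPermutationTest:
    @staticmethod
    def config(n_perm=20):
        return model.PipelineConfig(top_n=30, n_splits=8, top_k=10,
                                    n_outer=3, grid=TINY_GRID,
                                    n_permutations=n_perm)

    def test_p_on_value_grid_and_length(self, small_relabund, small_cohort):
        y = small_cohort.metadata.loc[small_relabund.index, "response"]
        res = model.permutation_test(small_relabund, y, self.config(),
                                     seed=3)
        assert len(res.null_aucs) == 20
        assert res.p in {k / 20 for k in range(21)}

    def test_add_one_convention(self, small_relabund, small_cohort):
        y = small_cohort.metadata.loc[small_relabund.index, "response"]
        plain = model.permutation_test(small_relabund, y, self.config(10),
                                       seed=4)
        addone = model.permutation_test(small_relabund, y, self.config(10),
                                        seed=4, add_one=True)
        hits = int((plain.null_aucs >= plain.observed_auc).sum())
        assert plain.p == hits / 10
        assert addone.p == (hits + 1) / 11

    def test_strong_signal_beats_null(self):
        # a separable cohort should never be matched by label permutations
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 12)
        x = pd.DataFrame(rng.normal(size=(24, 30)),
                         columns=[f"ASV_{i:03d}" for i in range(30)])
        x["ASV_000"] = y + rng.normal(scale=0.01, size=24)
        res = model.permutation_test(x, y, self.config(20), seed=5)
        assert res.observed_auc == pytest.approx(1.0)
        assert res.p <= 0.05


class TestRankBiomarkers:
    @staticmethod
    def cv_with_importances(imps):
        return model.NestedCvResult(outer_split_aucs=[1.0], mean_auc=1.0,
                                    best_hyperparameters=[{}],
                                    mean_feature_importance=pd.Series(imps))

    def test_normalization_anchor_and_order(self):
        cv = self.cv_with_importances({"a": 0.2, "b": 0.6, "c": 0.4})
        rel = pd.DataFrame({"a": [1, 0], "b": [0, 1], "c": [1, 1]},
                           index=["s1", "s2"], dtype=float)
        out = model.rank_biomarkers(cv, rel, ["non_responder", "responder"])
        assert list(out.asv_id) == ["b", "c", "a"]
        assert out.normalized_importance.iloc[0] == 1.0
        assert (out.normalized_importance <= 1).all()

    def test_directions(self):
        cv = self.cv_with_importances({"up_nr": 0.5, "up_r": 0.4, "tie": 0.3})
        rel = pd.DataFrame({"up_nr": [0.1, 0.9], "up_r": [0.9, 0.1],
                            "tie": [0.5, 0.5]}, index=["s1", "s2"])
        out = model.rank_biomarkers(cv, rel, ["responder", "non_responder"])
        d = out.set_index("asv_id").direction
        assert d["up_nr"] == "non_response"
        assert d["up_r"] == "response"
        assert d["tie"] == "indeterminate"

    def test_planted_signal_direction_roundtrip(self, small_relabund,
                                                small_cohort):
        y = small_cohort.metadata.loc[small_relabund.index, "response"]
        truth = small_cohort.truth.set_index("asv_id")
        imp = pd.Series(0.01, index=small_relabund.columns)
        imp[truth.index] = 1.0
        cv = self.cv_with_importances(imp.to_dict())
        out = model.rank_biomarkers(cv, small_relabund, y,
                                    taxonomy=small_cohort.taxonomy, top_n=4)
        merged = out.set_index("asv_id").join(truth, rsuffix="_truth")
        assert (merged.direction == merged.direction_truth).all()
        assert merged.taxonomy.str.len().gt(0).all()


def test_run_pipeline_is_deterministic(small_relabund, small_cohort):
    y = small_cohort.metadata.loc[small_relabund.index, "response"]
    config = model.PipelineConfig(top_n=30, n_splits=8, top_k=10, n_outer=3,
                                  grid=TINY_GRID)
    sel1, cv1 = model.run_pipeline(small_relabund, y, config, seed=9)
    sel2, cv2 = model.run_pipeline(small_relabund, y, config, seed=9)
    assert sel1.selected_features == sel2.selected_features
    assert cv1.outer_split_aucs == cv2.outer_split_aucs
    pd.testing.assert_series_equal(cv1.mean_feature_importance,
                                   cv2.mean_feature_importance)
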