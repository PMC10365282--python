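import numpy as np
import pandas as pd
import pytest

from imquant import modeling as M
from imquant.phantoms import make_feature_dataset

from . import oracles


@pytest.fixture(scope="module")
def planted():
    return make_feature_dataset(n=200, p=50, n_informative=2, effect_size=2.0,
                                seed=0)


class TestSplit:
    def test_random_split_deterministic_and_stratified(self, planted):
        df, _ = planted
        s1 = M.split_data(df, M.SplitSpec("random_proportion", 0.7, seed=3))
        s2 = M.split_data(df, M.SplitSpec("random_proportion", 0.7, seed=3))
        assert (s1 == s2).all()
        tr = df[(s1 == "train").to_numpy()]
        assert abs(tr["label"].mean() - 0.5) < 0.05

    def test_kfold_partitions_exactly_once(self, planted):
        df, _ = planted
        folds = M.split_data(df, M.SplitSpec("cross_validation", k=5, seed=1))
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(len(df)))

    def test_custom_grouping_verbatim(self, planted):
        df, _ = planted
        df = df.copy()
        df["group"] = np.where(np.arange(len(df)) % 3 == 0, "test", "train")
        out = M.split_data(df, M.SplitSpec("custom"))
        assert (out == df["group"]).all()


class TestStandardize:
    def test_zscore_train_columns_standardized(self, planted):
        df, _ = planted
        tr, te = df.iloc[:150], df.iloc[150:]
        trs, tes, _ = M.standardize(tr, te, M.ScalerSpec("zscore"))
        cols = M.feature_columns(trs)
        assert np.allclose(trs[cols].mean(), 0, atol=1e-9)
        assert np.allclose(trs[cols].std(ddof=0), 1, atol=1e-9)

    def test_min_max_fit_on_train_only(self, planted):
        df, _ = planted
        tr, te = df.iloc[:100], df.iloc[100:]
        trs, tes, _ = M.standardize(tr, te, M.ScalerSpec("min_max"))
        cols = M.feature_columns(trs)
        assert trs[cols].to_numpy().min() >= -1e-12
        assert trs[cols].to_numpy().max() <= 1.0 + 1e-12
        assert tes[cols].to_numpy().max() > 1.0  # test rows may exceed

    def test_l2_rows_unit_norm(self, planted):
        df, _ = planted
        trs, _, _ = M.standardize(df, None, M.ScalerSpec("l2_norm"))
        norms = np.linalg.norm(trs[M.feature_columns(trs)].to_numpy(), axis=1)
        assert np.allclose(norms, 1.0)

    def test_boxcox_requires_positive(self, planted):
        df, _ = planted
        with pytest.raises(ValueError, match="positive"):
            M.standardize(df, None, M.ScalerSpec("boxcox"))


class TestSelection:
    def test_constant_column_dropped_by_variance_threshold(self, planted):
        df, _ = planted
        df = df.copy()
        df["feat_const"] = 3.0
        res = M.select_features(df, "variance_threshold", threshold=1e-12)
        assert "feat_const" not in res.selected

    def test_kbest_finds_planted_features(self):
        hits = 0
        for seed in range(20):
            df, truth = make_feature_dataset(200, 50, 2, 2.0, seed=seed)
            res = M.select_features(df, "kbest_univariate", k=2)
            hits += set(res.selected) == set(truth["informative"])
        assert hits >= 19  # >= 95% of seeds

    def test_lasso_large_penalty_keeps_nothing(self, planted):
        df, _ = planted
        res = M.select_features(df, "lasso", alpha=1e6)
        assert res.selected == []

    def test_reduction_outputs_component_scores(self, planted):
        df, _ = planted
        res = M.select_features(df, "pca", n_components=3)
        out = res.transform(df)
        assert [c for c in out.columns if c.startswith("pca_")] == \
            ["pca_0", "pca_1", "pca_2"]

    def test_k_too_large_rejected(self, planted):
        df, _ = planted
        with pytest.raises(ValueError, match="exceeds"):
            M.select_features(df, "kbest_univariate", k=500)


class TestClassifiers:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (80, 2))
        y = (X[:, 0] > 0).astype(int)
        df = pd.DataFrame(X, columns=["a", "b"])
        df["label"] = y
        return df

    def test_all_13_names_dispatch(self, separable):
        for name in M.CLASSIFIER_NAMES:
            clf = M.fit_classifier(separable, M.ClassifierSpec(name, seed=1))
            p = clf.predict_proba(separable[["a", "b"]].to_numpy())
            assert p.shape == (80, 2)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6), name
            assert (p >= 0).all() and (p <= 1).all(), name

    def test_decision_tree_fits_separable_data(self, separable):
        clf = M.fit_classifier(separable, M.ClassifierSpec("decision_tree"))
        pred = clf.predict(separable[["a", "b"]].to_numpy())
        assert (pred == separable["label"].to_numpy()).mean() == 1.0

    def test_unknown_name_lists_the_13(self):
        with pytest.raises(ValueError) as exc:
            M.ClassifierSpec("mlp")
        for name in M.CLASSIFIER_NAMES:
            assert name in str(exc.value)

    def test_seeded_determinism(self, separable):
        a = M.fit_classifier(separable, M.ClassifierSpec("random_forest", seed=5))
        b = M.fit_classifier(separable, M.ClassifierSpec("random_forest", seed=5))
        X = separable[["a", "b"]].to_numpy()
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_single_class_rejected(self, separable):
        df = separable[separable["label"] == 1]
        with pytest.raises(ValueError, match="2 classes"):
            M.fit_classifier(df, M.ClassifierSpec("knn"))


class TestEvaluateClassifier:
    def test_worked_auc_example(self):
        rep = M.evaluate_classifier([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert rep.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        rep = M.evaluate_classifier([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert rep.auc == 1.0

    def test_confusion_derived_rates(self):
        scores = np.r_[np.full(40, 0.9), np.full(10, 0.1),
                       np.full(5, 0.9), np.full(45, 0.1)]
        labels = np.r_[np.ones(50), np.zeros(50)].astype(int)
        rep = M.evaluate_classifier(scores, labels)
        assert rep.confusion == {"tp": 40, "fp": 5, "tn": 45, "fn": 10}
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.specificity == pytest.approx(0.9)
        assert rep.accuracy == pytest.approx(0.85)

    def test_auc_equals_pair_counting_with_ties(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 50))
            scores = rng.integers(0, 6, n) / 5.0  # ties guaranteed
            labels = rng.integers(0, 2, n)
            if len(set(labels)) < 2:
                continue
            rep = M.evaluate_classifier(scores, labels)
            assert rep.auc == pytest.approx(
                oracles.auc_pair_counting(scores, labels), abs=1e-12)

    def test_delong_ci_contains_auc_and_shrinks(self, rng):
        def width(n):
            s = np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)]
            l = np.r_[np.ones(n), np.zeros(n)].astype(int)
            auc, lo, hi = M.delong_ci(s, l)
            assert lo <= auc <= hi
            return hi - lo

        assert width(500) < width(50)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            M.evaluate_classifier([0.2, 0.8], [1, 1])


class TestDecisionCurve:
    def test_treat_none_is_zero(self, rng):
        labels = rng.integers(0, 2, 100)
        dc = M.decision_curve(rng.random(100), labels)
        assert np.all(dc.net_benefit_none == 0.0)

    def test_treat_all_crosses_zero_at_prevalence(self, rng):
        labels = np.r_[np.ones(30), np.zeros(70)].astype(int)
        prev = labels.mean()
        dc = M.decision_curve(rng.random(100), labels,
                              thresholds=np.array([prev]))
        assert dc.net_benefit_all[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_classifier_net_benefit_is_prevalence(self):
        labels = np.r_[np.ones(20), np.zeros(80)].astype(int)
        scores = labels * 0.9 + 0.05
        dc = M.decision_curve(scores, labels,
                              thresholds=np.linspace(0.1, 0.9, 9))
        np.testing.assert_allclose(dc.net_benefit_model, 0.2, atol=1e-12)

    def test_clinical_impact_counts(self):
        labels = np.r_[np.ones(20), np.zeros(80)].astype(int)
        scores = labels * 0.9 + 0.05
        dc = M.decision_curve(scores, labels, thresholds=np.array([0.5]))
        assert dc.high_risk_per_1000[0] == pytest.approx(200.0)
        assert dc.events_per_1000[0] == pytest.approx(200.0)

    def test_thresholds_outside_unit_interval_rejected(self, rng):
        with pytest.raises(ValueError):
            M.decision_curve(rng.random(10), rng.integers(0, 2, 10),
                             thresholds=np.array([0.0, 0.5]))


class TestEvaluateRegressor:
    def test_perfect_predictions(self):
        rep = M.evaluate_regressor([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (rep.mae, rep.mse, rep.r2) == (0.0, 0.0, 1.0)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_mean_prediction_zero_r2(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        rep = M.evaluate_regressor(np.full(4, t.mean()), t)
        assert rep.r2 == pytest.approx(0.0)

    def test_hand_computed_errors(self):
        rep = M.evaluate_regressor([1.0, 2.0, 5.0], [1.0, 2.0, 3.0])
        assert rep.mae == pytest.approx(2.0 / 3.0)
        assert rep.mse == pytest.approx(4.0 / 3.0)

    def test_constant_targets_marked_undefined(self):
        rep = M.evaluate_regressor([1.0, 2.0], [3.0, 3.0])
        assert rep.r2 is None and rep.pearson_r is None
        assert rep.mse > 0


class TestNomogram:
    def test_anchor_variable_spans_100_points(self):
        nm = M.build_nomogram({"a": 1.0, "b": 0.5}, 0.0,
                              {"a": (0.0, 1.0), "b": (0.0, 1.0)})
        assert nm.points("a", 1.0) == pytest.approx(100.0)
        assert nm.points("b", 1.0) == pytest.approx(50.0)

    def test_reference_values_give_zero_points(self):
        nm = M.build_nomogram({"a": 2.0, "b": -1.0}, 0.5,
                              {"a": (0.0, 2.0), "b": (-1.0, 3.0)})
        total, _ = M.nomogram_score(nm, {"a": 0.0, "b": 3.0})
        assert total == pytest.approx(0.0)

    def test_points_nonnegative_over_range(self):
        nm = M.build_nomogram({"a": 2.0, "b": -1.5}, 0.0,
                              {"a": (-1.0, 2.0), "b": (-2.0, 4.0)})
        for v, (lo, hi) in nm.ranges.items():
            for x in np.linspace(lo, hi, 7):
                assert nm.points(v, x) >= -1e-12

    def test_probability_consistent_with_logistic_model(self, rng):
        coef = {"a": 0.8, "b": -0.3, "c": 1.7}
        nm = M.build_nomogram(coef, -0.4, {v: (-2.0, 2.0) for v in coef})
        for _ in range(5):
            sample = {v: float(rng.uniform(-2, 2)) for v in coef}
            _, prob = M.nomogram_score(nm, sample)
            lin = -0.4 + sum(coef[v] * sample[v] for v in coef)
            assert prob == pytest.approx(1 / (1 + np.exp(-lin)), abs=1e-10)

    def test_all_zero_coefficients_rejected(self):
        with pytest.raises(ValueError):
            M.build_nomogram({"a": 0.0}, 0.0, {"a": (0.0, 1.0)})
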