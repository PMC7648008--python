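"""Cross-validation plans, pooled metrics and permutation inference."""

import numpy as np

import pytest

from mkldecode import evaluation
from mkldecode.evaluation import (
    classification_metrics,
    make_fold_plan,
    permutation_test,
    permute_classification_labels,
    regression_metrics,
    run_nested_cv,
)
from mkldecode.kernels import build_kernelset, RegionFeatureBlock


def _subjects(n):
    return [f"s{i:02d}" for i in range(n)]


class TestFoldPlan:
    def test_loso_has_one_fold_per_subject(self):
        plan = make_fold_plan(_subjects(38), "loso")
        assert plan.n_folds == 38
        assert all(len(te) == 1 for _, te in plan.folds)

    def test_kfold_38_subjects_sizes(self):
        plan = make_fold_plan(_subjects(38), "kfold", k=10, seed=0)
        sizes = sorted(len(te) for _, te in plan.folds)
        assert sizes == [3, 3, 4, 4, 4, 4, 4, 4, 4, 4]

    def test_test_sets_partition_subjects(self):
        for scheme, kw in (("loso", {}), ("kfold", {"k": 5})):
            plan = make_fold_plan(_subjects(17), scheme, seed=1, **kw)
            test_union = sorted(s for _, te in plan.folds for s in te)
            assert test_union == _subjects(17)

    def test_inner_plans_exclude_outer_test_subjects(self):
        plan = make_fold_plan(_subjects(20), "kfold", k=5, seed=2)
        for (train, test), inner in zip(plan.folds, plan.inner):
            inner_subjects = {s for f in inner.folds for s in f[0] + f[1]}
            assert inner_subjects == set(train)
            assert not inner_subjects & set(test)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(_subjects(2), "loso")
        with pytest.raises(ValueError):
            make_fold_plan(_subjects(5), "kfold", k=10)

    def test_kfold_assignment_depends_on_seed(self):
        p1 = make_fold_plan(_subjects(20), "kfold", k=5, seed=0)
        p2 = make_fold_plan(_subjects(20), "kfold", k=5, seed=1)
        assert p1.folds != p2.folds


class TestClassificationMetrics:
    def test_balanced_accuracy_is_mean_of_class_accuracies(self):
        """24/38 and 31/38 correct give the printed 63.16 / 81.58 / 72.37."""
        y = np.array([1.0] * 38 + [-1.0] * 38)
        scores = np.concatenate([
            np.where(np.arange(38) < 24, 1.0, -1.0),     # 24 threat correct
            np.where(np.arange(38) < 31, -1.0, 1.0),     # 31 neutral correct
        ])
        m, _ = classification_metrics(y, scores)
        assert round(m["accuracy_class1"], 2) == 63.16
        assert round(m["accuracy_class2"], 2) == 81.58
        assert round(m["balanced_accuracy"], 2) == 72.37
        assert np.isclose(m["balanced_accuracy"],
                          (m["accuracy_class1"] + m["accuracy_class2"]) / 2)

    def test_18_of_38_each_class_gives_47_37(self):
        y = np.array([1.0] * 38 + [-1.0] * 38)
        scores = np.concatenate([
            np.where(np.arange(38) < 18, 1.0, -1.0),
            -np.where(np.arange(38) < 18, 1.0, -1.0)])
        m, _ = classification_metrics(y, scores)
        assert round(m["accuracy_class1"], 2) == 47.37
        assert round(m["balanced_accuracy"], 2) == 47.37

    def test_loso_accuracies_are_multiples_of_100_over_n(self):
        rng = np.random.default_rng(0)
        y = np.array([1.0, -1.0] * 38)
        scores = rng.normal(size=76)
        m, _ = classification_metrics(y, scores)
        for key in ("accuracy_class1", "accuracy_class2"):
            assert np.isclose((m[key] / (100 / 38)) % 1, 0, atol=1e-9) or \
                np.isclose((m[key] / (100 / 38)) % 1, 1, atol=1e-9)

    def test_auc_limits(self):
        y = np.array([1.0] * 5 + [-1.0] * 5)
        perfect = np.array([2, 3, 4, 5, 6, -2, -3, -1, -4, -5], dtype=float)
        m, (fpr, tpr) = classification_metrics(y, perfect)
        assert m["auc"] == 1.0
        assert fpr[0] == 0.0 and tpr[-1] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.ones(4), np.ones(4))


class TestRegressionMetrics:
    def test_r_squared_is_r_squared(self):
        """Constructed r = 0.56 reproduces the printed R^2 = 0.31."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        z = rng.normal(size=200)
        z = z - z.mean() - x * (x @ z) / (x @ x)      # orthogonal to x
        r_target = 0.56
        y = r_target * x / x.std() + np.sqrt(1 - r_target ** 2) * z / z.std()
        m = regression_metrics(y, x)
        assert round(m["r"], 2) == 0.56
        assert round(m["r2"], 2) == 0.31
        assert np.isclose(m["r2"], m["r"] ** 2)

    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = regression_metrics(y, y)
        assert m["r"] == pytest.approx(1.0)
        assert m["mse"] == 0.0

    def test_constant_shift(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = regression_metrics(y, y + 2.0)
        assert m["r"] == pytest.approx(1.0)
        assert m["mse"] == pytest.approx(4.0)

    def test_zero_variance_reports_nan_r_and_valid_mse(self):
        with pytest.warns(UserWarning, match="zero variance"):
            m = regression_metrics(np.array([1.0, 1.0, 1.0]),
                                   np.array([0.0, 1.0, 2.0]))
        assert np.isnan(m["r"])
        assert m["mse"] == pytest.approx(2.0 / 3.0)


class TestPermutationTest:
    def test_floor_p_value_is_one_over_nperm_plus_one(self):
        """Observed metric beating all 100 permutations: p = 0.01 (2 d.p.)."""
        rng = np.random.default_rng(0)

        def closure(y):
            return {"balanced_accuracy": float(np.abs(y).sum() % 50)}

        observed = {"balanced_accuracy": 1e9}
        rep = permutation_test(closure, np.arange(40, dtype=float),
                               "regression", observed_metrics=observed,
                               n_perm=100, seed=0)
        assert rep.p_values["balanced_accuracy"] == pytest.approx(1 / 101)
        assert round(rep.p_values["balanced_accuracy"], 2) == 0.01

    def test_all_ties_give_p_one(self):
        def closure(y):
            return {"metric": 1.0}

        rep = permutation_test(closure, np.arange(10, dtype=float),
                               "regression", observed_metrics={"metric": 1.0},
                               n_perm=50, seed=0)
        assert rep.p_values["metric"] == 1.0

    def test_mse_direction_reversed(self):
        vals = iter([5.0] * 30)

        def closure(y):
            return {"mse": next(vals)}

        rep = permutation_test(closure, np.arange(10, dtype=float),
                               "regression", observed_metrics={"mse": 1.0},
                               n_perm=30, seed=0)
        assert rep.p_values["mse"] == pytest.approx(1 / 31)
        rep2_vals = iter([0.5] * 30)

        def closure2(y):
            return {"mse": next(rep2_vals)}

        rep2 = permutation_test(closure2, np.arange(10, dtype=float),
                                "regression", observed_metrics={"mse": 1.0},
                                n_perm=30, seed=0)
        assert rep2.p_values["mse"] == 1.0

    def test_within_subject_permutation_preserves_pairs(self):
        y = np.array([1.0, -1.0] * 6)
        subjects = np.repeat(_subjects(6), 2)
        rng = np.random.default_rng(0)
        seen_flip = False
        for _ in range(20):
            perm = permute_classification_labels(y, subjects, rng)
            for s in np.unique(subjects):
                rows = subjects == s
                assert sorted(perm[rows]) == [-1.0, 1.0]
            seen_flip |= not np.array_equal(perm, y)
        assert seen_flip


class TestNestedCV:
    @staticmethod
    def _paired_problem(n_subjects, delta, seed, p=30):
        """Two samples per subject (threat/neutral) with a mean shift."""
        rng = np.random.default_rng(seed)
        subjects = np.repeat(_subjects(n_subjects), 2)
        y = np.array([1.0, -1.0] * n_subjects)
        X = rng.standard_normal((2 * n_subjects, p))
        X[y > 0] += delta
        blocks = [RegionFeatureBlock(region_id=1, data=X,
                                     voxel_coords=np.zeros((p, 3), int))]
        raw = build_kernelset(blocks, list(subjects), ["c"] * len(y))
        return raw, y

    def test_separable_data_scores_perfectly(self):
        raw, y = self._paired_problem(12, delta=4.0, seed=0)
        plan = make_fold_plan(_subjects(12), "kfold", k=4, seed=0)
        rep = run_nested_cv(raw, y, "classification", plan,
                            C_grid=(0.1, 1.0))
        assert rep.metrics["balanced_accuracy"] == 100.0

    def test_noiseless_linear_regression_r_above_095(self):
        rng = np.random.default_rng(1)
        n, p = 16, 10
        X = rng.standard_normal((n, p))
        w = rng.standard_normal(p)
        y = X @ w
        blocks = [RegionFeatureBlock(region_id=1, data=X,
                                     voxel_coords=np.zeros((p, 3), int))]
        raw = build_kernelset(blocks, _subjects(n), ["c"] * n)
        plan = make_fold_plan(_subjects(n), "kfold", k=4, seed=0)
        rep = run_nested_cv(raw, y, "regression", plan,
                            C_grid=(1.0, 10.0, 100.0))
        assert rep.metrics["r"] >= 0.95

    def test_null_labels_score_near_chance(self):
        """Labels independent of data: mean balanced accuracy over 20
        seeds inside the binomial 99% band around 50%."""
        accs = []
        for seed in range(20):
            raw, y = self._paired_problem(10, delta=0.0, seed=seed, p=15)
            plan = make_fold_plan(_subjects(10), "kfold", k=5, seed=seed)
            rep = run_nested_cv(raw, y, "classification", plan,
                                fixed_C=1.0)
            accs.append(rep.metrics["balanced_accuracy"] / 100.0)
        n_pred = 20 * 20       # 20 predictions per seed
        band = 2.576 * np.sqrt(0.25 / n_pred)
        assert abs(np.mean(accs) - 0.5) <= band

    def test_outer_test_targets_never_influence_training(self):
        """No-leakage: corrupting outer-test targets leaves the chosen
        hyperparameters and fold weights bitwise unchanged."""
        raw, y = self._paired_problem(10, delta=1.0, seed=3)
        plan = make_fold_plan(_subjects(10), "kfold", k=5, seed=0)
        rep1 = run_nested_cv(raw, y, "classification", plan,
                             C_grid=(0.1, 1.0))
        y2 = y.copy()
        test_subjects = plan.folds[0][1]
        subj = np.array(raw.sample_subjects)
        rows = np.isin(subj, test_subjects)
        y2[rows] *= -1.0
        rep2 = run_nested_cv(raw, y2, "classification", plan,
                             C_grid=(0.1, 1.0))
        assert rep1.chosen_C[0] == rep2.chosen_C[0]
        assert np.array_equal(rep1.fold_weights["fold_0"].to_numpy(),
                              rep2.fold_weights["fold_0"].to_numpy())

    def test_metrics_recomputable_from_stored_predictions(self):
        raw, y = self._paired_problem(10, delta=1.0, seed=4)
        plan = make_fold_plan(_subjects(10), "kfold", k=5, seed=1)
        rep = run_nested_cv(raw, y, "classification", plan, C_grid=(1.0,))
        again = rep.recompute_metrics()
        for key, val in rep.metrics.items():
            assert again[key] == pytest.approx(val)

    def test_one_prediction_per_subject_per_class(self):
        raw, y = self._paired_problem(10, delta=1.0, seed=5)
        plan = make_fold_plan(_subjects(10), "loso")
        rep = run_nested_cv(raw, y, "classification", plan, fixed_C=1.0)
        counts = rep.predictions.groupby(["subject", "y_true"]).size()
        assert (counts == 1).all()
        assert len(rep.predictions) == 20
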