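import numpy as np
import pytest

from herbprint.featurize import Dataset, MzGrid, build_dataset, featurize_peak_table, fold
from herbprint.autoencode import Autoencoder
from herbprint.evaluate import (
    compute_metrics,
    fit_gaussian_nb,
    fit_l1_logreg,
    make_cv_plan,
    neighbor_analysis,
    run_cv,
    variable_importance_curve,
)
from herbprint.simulate import make_species_library, simulate_peaklists


class TestCVPlan:
    def test_stratification_within_one_sample(self):
        rng = np.random.default_rng(0)
        y = np.repeat(["a", "b", "c"], [40, 25, 10])[rng.permutation(75)]
        plan = make_cv_plan(y, n_folds=5, n_repeats=5, seed=1)
        for r in range(5):
            for f in range(5):
                test = plan.assignment[r] == f
                for cls, total in zip(*np.unique(y, return_counts=True)):
                    got = np.sum(test & (y == cls))
                    assert abs(got - total / 5) <= 1

    def test_every_sample_tested_once_per_repeat(self):
        y = np.repeat(["a", "b"], 20)
        plan = make_cv_plan(y, seed=0)
        assert plan.assignment.shape == (5, 40)
        assert all(set(np.unique(plan.assignment[r])) == set(range(5))
                   for r in range(5))

    def test_yields_25_splits(self):
        plan = make_cv_plan(np.repeat(["a", "b"], 20), seed=0)
        assert sum(1 for _ in plan.splits()) == 25

    def test_deterministic_given_seed(self):
        y = np.repeat(["a", "b", "c"], 15)
        p1 = make_cv_plan(y, seed=3)
        p2 = make_cv_plan(y, seed=3)
        np.testing.assert_array_equal(p1.assignment, p2.assignment)

    def test_small_class_rejected_at_plan_time(self):
        y = np.array(["a"] * 20 + ["b"] * 3)
        with pytest.raises(ValueError, match="fewer than 5"):
            make_cv_plan(y, n_folds=5)


class TestL1LogReg:
    def test_separable_toy_reaches_full_accuracy(self):
        Z = np.array([[0.0, 0], [0, 1], [5, 0], [5, 1]])
        y = np.array(["a", "a", "b", "b"])
        clf = fit_l1_logreg(Z, y, seed=0)
        assert np.mean(clf.predict(Z) == y) == 1.0

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(30, 5))
        y = rng.choice(["a", "b", "c"], size=30)
        proba = fit_l1_logreg(Z, y, seed=0).predict_proba(Z)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_extreme_penalty_collapses_to_majority(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(40, 5))
        y = np.array(["maj"] * 30 + ["min"] * 10)
        clf = fit_l1_logreg(Z, y, strength=1e8, seed=0)
        assert np.all(np.abs(clf.estimator.coef_) < 1e-6)
        assert set(clf.predict(Z)) == {"maj"}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_l1_logreg(np.zeros((4, 2)), np.array(["a"] * 4))


class TestGaussianNB:
    def _fit_1d(self):
        # two 1-D Gaussian classes: means 0 and 4, sd 1, equal priors
        rng = np.random.default_rng(0)
        Z = np.concatenate([rng.normal(0, 1, 500), rng.normal(4, 1, 500)])[:, None]
        y = np.repeat(["a", "b"], 500)
        clf = fit_gaussian_nb(Z, y)
        # use exact population parameters for the closed-form checks
        clf.estimator.theta_ = np.array([[0.0], [4.0]])
        clf.estimator.var_ = np.array([[1.0], [1.0]])
        clf.estimator.class_prior_ = np.array([0.5, 0.5])
        return clf

    def test_midpoint_query_is_equivocal(self):
        proba = self._fit_1d().predict_proba([[2.0]])[0]
        np.testing.assert_allclose(proba, [0.5, 0.5], atol=1e-9)

    def test_closed_form_gaussian_ratio_at_zero(self):
        proba = self._fit_1d().predict_proba([[0.0]])[0]
        assert proba[0] == pytest.approx(1.0 / (1.0 + np.exp(-8.0)), abs=1e-9)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(60, 4))
        y = rng.choice(["a", "b", "c"], size=60)
        proba = fit_gaussian_nb(Z, y).predict_proba(Z)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_singleton_class_error_names_class(self):
        Z = np.zeros((5, 2))
        y = np.array(["a", "a", "a", "a", "lonely"])
        with pytest.raises(ValueError, match="lonely"):
            fit_gaussian_nb(Z, y)


def _ranked_from_pred(y_pred, classes):
    """Two-column ranked store: prediction first, then some other class."""
    other = [classes[0] if p != classes[0] else classes[1] for p in y_pred]
    return np.stack([y_pred, other], axis=1)


class TestMetrics:
    def test_perfect_ranking(self):
        y = np.array(["a", "b", "a"])
        m = compute_metrics(y, _ranked_from_pred(y, ["a", "b"]))
        assert m["accuracy"] == 1.0
        assert m["weighted_f1"] == 1.0
        assert all(v == 1.0 for v in m["topn"].values())

    def test_hand_computed_two_class_example(self):
        # confusion [[8, 2], [4, 6]] for classes (c1, c2)
        y_true = np.array(["c1"] * 10 + ["c2"] * 10)
        y_pred = np.array(["c1"] * 8 + ["c2"] * 2 + ["c1"] * 4 + ["c2"] * 6)
        m = compute_metrics(y_true, _ranked_from_pred(y_pred, ["c1", "c2"]))
        assert m["accuracy"] == pytest.approx(0.7)
        f1_c1 = 2 * (8 / 12) * (8 / 10) / (8 / 12 + 8 / 10)
        f1_c2 = 2 * (6 / 8) * (6 / 10) / (6 / 8 + 6 / 10)
        assert m["weighted_f1"] == pytest.approx((f1_c1 + f1_c2) / 2)
        assert m["confusion"].to_numpy().tolist() == [[8, 2], [4, 6]]

    def test_confusion_row_sums_are_class_counts(self):
        rng = np.random.default_rng(4)
        y_true = rng.choice(["a", "b", "c"], size=50)
        y_pred = rng.choice(["a", "b", "c"], size=50)
        m = compute_metrics(y_true, _ranked_from_pred(y_pred, ["a", "b"]))
        row_sums = m["confusion"].sum(axis=1)
        for cls in ["a", "b", "c"]:
            assert row_sums[cls] == np.sum(y_true == cls)

    def test_topn_non_decreasing(self):
        rng = np.random.default_rng(5)
        classes = np.array(["a", "b", "c", "d", "e"])
        y_true = rng.choice(classes, size=40)
        ranked = np.stack([rng.permutation(classes) for _ in range(40)])
        m = compute_metrics(y_true, ranked)
        vals = [m["topn"][n] for n in sorted(m["topn"])]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_undefined_f1_class_warns(self):
        y_true = np.array(["a", "a"])
        ranked = _ranked_from_pred(np.array(["a", "a"]), ["a", "b"])
        with pytest.warns(UserWarning, match="F1 undefined"):
            compute_metrics(y_true, ranked, labels=np.array(["a", "b", "ghost"]))


class TestNeighborAnalysis:
    def test_perfect_classifier_top1_is_self(self):
        y = np.array(["a", "b", "a", "b"])
        ranked = _ranked_from_pred(y, ["a", "b"])
        table = neighbor_analysis(y, ranked, n=1)
        assert table["a"] == [("a", 2)]
        assert table["b"] == [("b", 2)]

    def test_counts_sum_to_n_times_samples(self):
        rng = np.random.default_rng(6)
        classes = np.array(["a", "b", "c"])
        y = rng.choice(classes, size=30)
        ranked = np.stack([rng.permutation(classes) for _ in range(30)])
        table = neighbor_analysis(y, ranked, n=2)
        for cls in classes:
            total = sum(c for _, c in table[cls])
            assert total == 2 * np.sum(y == cls)

    def test_symmetric_confusers_find_each_other(self):
        y = np.array(["a"] * 5 + ["b"] * 5)
        ranked = np.array([["b", "a", "c"]] * 5 + [["a", "b", "c"]] * 5)
        table = neighbor_analysis(y, ranked, n=1)
        assert table["a"][0][0] == "b"
        assert table["b"][0][0] == "a"

    def test_too_many_ranks_requested(self):
        with pytest.raises(ValueError, match="ranks"):
            neighbor_analysis(np.array(["a"]), np.array([["a", "b"]]), n=3)


@pytest.fixture(scope="module")
def tiny_dataset():
    """4 species x 10 replicates, low noise, small marker sets."""
    lib = make_species_library(4, n_markers=10, n_shared=10, seed=3)
    peaks = simulate_peaklists(lib, n_replicates=10, dropout=0.05, seed=4)
    return build_dataset(featurize_peak_table(peaks), min_samples_per_class=1)


class TestRunCV:
    def test_shared_plan_and_report_shape(self, tiny_dataset):
        y = tiny_dataset.labels()
        plan = make_cv_plan(y, n_folds=2, n_repeats=2, seed=0)
        cfg = {"r2": 5, "n_iter": 40}
        rep = run_cv(tiny_dataset, "sntd_pa", plan, cfg, eval_train=False)
        # 2 repeats x 2 folds = 4 fitted evaluations per metric
        accs = rep.records.query("metric == 'accuracy' and split == 'test'")
        assert len(accs) == 4
        # every sample scored exactly once per repeat
        test_rows = rep.ranked.query("split == 'test' and rank == 1")
        counts = test_rows.groupby(["repeat", "sample_id"]).size()
        assert (counts == 1).all()
        assert set(test_rows.groupby("repeat")["sample_id"].nunique()) == {y.size}

    def test_identical_plan_across_methods(self, tiny_dataset):
        y = tiny_dataset.labels()
        p1 = make_cv_plan(y, n_folds=2, n_repeats=1, seed=7)
        p2 = make_cv_plan(y, n_folds=2, n_repeats=1, seed=7)
        np.testing.assert_array_equal(p1.assignment, p2.assignment)

    def test_bn_arm_runs_and_scores(self, tiny_dataset):
        plan = make_cv_plan(tiny_dataset.labels(), n_folds=2, n_repeats=1, seed=1)
        rep = run_cv(tiny_dataset, "large_bn", plan, eval_train=False)
        assert rep.median("accuracy") > 0.8
        tops = rep.topn_table()
        vals = tops[[f"top{n}" for n in range(1, 5)]].to_numpy()
        assert np.all(np.diff(vals) >= 0)

    def test_ae_arm_runs(self, tiny_dataset):
        plan = make_cv_plan(tiny_dataset.labels(), n_folds=2, n_repeats=1, seed=2)
        cfg = {"ae_epochs": 5, "ae_n_encoding_layers": 2}
        rep = run_cv(tiny_dataset, "ae_logreg", plan, cfg, eval_train=False)
        assert set(rep.records["metric"]) >= {"accuracy", "weighted_f1", "top1"}

    def test_organ_labels_need_only_column_selection(self):
        lib_root = make_species_library(2, n_markers=10, n_shared=5, seed=8)
        lib_leaf = make_species_library(2, n_markers=10, n_shared=5, seed=9)
        import pandas as pd

        peaks = pd.concat([
            simulate_peaklists(lib_root, 8, 0.05, seed=1, organ="root"),
            simulate_peaklists(lib_leaf, 8, 0.05, seed=2, organ="leaf"),
        ])
        peaks["sample_id"] = peaks["organ"] + "_" + peaks["sample_id"]
        ds = build_dataset(featurize_peak_table(peaks), min_samples_per_class=1,
                           label_by="organ")
        assert set(ds.class_map) == {"root", "leaf"}
        plan = make_cv_plan(ds.labels(), n_folds=2, n_repeats=1, seed=0)
        rep = run_cv(ds, "sntd_pa", plan, {"r2": 5, "n_iter": 30}, eval_train=False)
        assert rep.median("accuracy") > 0.8


class TestVariableImportance:
    @pytest.fixture(scope="class")
    def planted(self):
        """16 marker bins of 320 carry all class signal; rest is tiny noise."""
        rng = np.random.default_rng(0)
        d, n_cls, per = 320, 3, 30
        markers = rng.choice(d, size=16, replace=False)
        X, y = [], []
        for c in range(n_cls):
            own = markers[c::3]
            for _ in range(per):
                v = rng.uniform(0, 0.05, size=d)
                v[own] = rng.uniform(0.7, 1.0, size=own.size)
                X.append(v)
                y.append(c)
        X = np.asarray(X)
        ds = Dataset(
            fold(X, d // 2, 2), np.asarray(y),
            {f"c{i}": i for i in range(n_cls)},
            [f"s{i}" for i in range(len(y))],
            MzGrid(0, d // 2), "sample_max", 0,
        )
        ae = Autoencoder(n_encoding_layers=2, epochs=60, lr=1e-2, seed=0).fit(X)
        return ae, ds, markers

    def test_curve_length_matches_steps(self, planted):
        ae, ds, _ = planted
        curve = variable_importance_curve(ae, ds, step_sizes=[8, 16, 320], seed=0)
        assert len(curve) == 3

    def test_full_set_identical_for_both_orders(self, planted):
        ae, ds, _ = planted
        d = variable_importance_curve(ae, ds, "descending", [320], seed=0)
        a = variable_importance_curve(ae, ds, "ascending", [320], seed=0)
        assert d["accuracy"].iloc[0] == a["accuracy"].iloc[0]

    def test_heavy_variables_carry_the_signal(self, planted):
        ae, ds, _ = planted
        steps = [16, 320]  # 5% of the variables, then all
        desc = variable_importance_curve(ae, ds, "descending", steps, seed=0)
        asc = variable_importance_curve(ae, ds, "ascending", steps, seed=0)
        full = desc["accuracy"].iloc[-1]
        assert desc["accuracy"].iloc[0] >= full - 0.02
        assert asc["accuracy"].iloc[0] < full - 0.02

    def test_oversized_step_clipped_with_warning(self, planted):
        ae, ds, _ = planted
        with pytest.warns(UserWarning, match="clipped"):
            curve = variable_importance_curve(ae, ds, step_sizes=[5000], seed=0)
        assert curve["n_variables"].iloc[0] == 320
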