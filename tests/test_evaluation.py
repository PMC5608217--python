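import numpy as np
import pandas as pd
import pytest

from frmt import (
    ConfusionCounts,
    CoverageError,
    EvaluationError,
    ParameterError,
    StratificationError,
    SyntheticConfig,
    auc,
    best_method_summary,
    cross_validate,
    generate,
    mcc,
    run_evaluation_grid,
    winning_frequency,
)
from frmt.evaluation import (
    FuzzyGaussianClassifier,
    make_classifier,
    _stratified_folds,
)
from oracles import brute_auc, brute_mcc


class TestMcc:
    def test_perfect_prediction(self):
        assert mcc(ConfusionCounts(tp=50, fp=0, tn=50, fn=0)) == 1.0

    def test_random_prediction(self):
        assert mcc(ConfusionCounts(tp=25, fp=25, tn=25, fn=25)) == 0.0

    def test_total_disagreement(self):
        assert mcc(ConfusionCounts(tp=0, fp=30, tn=0, fn=30)) == -1.0

    def test_worked_example(self):
        value = mcc(ConfusionCounts(tp=45, fp=10, tn=40, fn=5))
        assert value == pytest.approx(1750 / np.sqrt(55 * 50 * 50 * 45), abs=1e-12)
        assert value == pytest.approx(0.7035, abs=5e-4)

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(tp=10, fp=0, tn=0, fn=0)) == 0.0

    def test_symmetry_under_class_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(0, 20, size=4)
            a = mcc(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            b = mcc(ConfusionCounts(int(tn), int(fn), int(tp), int(fp)))
            assert a == pytest.approx(b, abs=1e-12)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 30, size=4))
            assert mcc(ConfusionCounts(tp, fp, tn, fn)) == pytest.approx(
                brute_mcc(tp, fp, tn, fn), abs=1e-12
            )

    def test_counts_from_predictions(self):
        c = ConfusionCounts.from_predictions(
            np.array([1, 1, -1, -1]), np.array([1, -1, -1, 1])
        )
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)
        assert c.total == 4


class TestAuc:
    def test_perfect_separation(self):
        assert auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, -1, -1])) == 1.0

    def test_constant_scores(self):
        assert auc(np.zeros(6), np.array([1, 1, 1, -1, -1, -1])) == 0.5

    def test_three_of_four_pairs(self):
        value = auc(np.array([0.9, 0.8, 0.4, 0.3]), np.array([1, -1, 1, -1]))
        assert value == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_matches_pair_counting(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(4, 20))
            scores = np.round(rng.random(n), 1)  # induce ties
            labels = np.where(rng.random(n) < 0.5, 1, -1)
            if len(set(labels)) < 2:
                labels[0], labels[1] = 1, -1
            assert auc(scores, labels) == pytest.approx(
                brute_auc(scores, labels), abs=1e-12
            )


class TestClassifierAdapters:
    @pytest.mark.parametrize("name", ["svm", "rf", "dt", "lda", "nb", "fl", "knn"])
    def test_roster_fits_and_scores(self, name):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 4))
        y = np.where(X[:, 0] + 0.3 * rng.standard_normal(40) > 0, 1, -1)
        clf = make_classifier(name, seed=0).fit(X, y)
        pred = clf.predict(X)
        assert set(np.unique(pred)) <= {1, -1}
        scores = clf.decision_scores(X)
        assert scores.shape == (40,)
        assert auc(scores, y) > 0.7  # oriented toward the positive class

    def test_unknown_classifier(self):
        with pytest.raises(ParameterError):
            make_classifier("xgboost")

    def test_fuzzy_classifier_separates_shifted_gaussians(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(2, 1, (30, 3)), rng.normal(-2, 1, (30, 3))])
        y = np.array([1] * 30 + [-1] * 30)
        clf = FuzzyGaussianClassifier().fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.95
        assert clf.decision_function(X[:1]).shape == (1,)


class TestStratification:
    def test_fold_proportions(self):
        labels = np.array([1] * 33 + [-1] * 67)
        splits = _stratified_folds(labels, 10, rng_seed=4)
        assert len(splits) == 10
        for _, test_idx in splits:
            pos = int((labels[test_idx] == 1).sum())
            neg = int((labels[test_idx] == -1).sum())
            # global proportions are 3.3 / 6.7 per fold of 10
            assert abs(pos - 3.3) <= 1.0
            assert abs(neg - 6.7) <= 1.0

    def test_minority_class_too_small(self):
        labels = np.array([1] * 3 + [-1] * 50)
        with pytest.raises(StratificationError):
            _stratified_folds(labels, 10, rng_seed=0)


def separable_dataset(seed=0):
    cfg = SyntheticConfig(
        n_early=30, n_advanced=30, n_features=6, n_informative=3,
        effect_size=6.0, seed=seed,
    )
    return generate(cfg)[0]


class TestCrossValidate:
    def test_perfectly_separable_scores_one(self):
        data = separable_dataset()
        mccs, aucs = cross_validate(
            data, "ttest", 3, "lda", n_folds=5, n_repeats=2, seed=1
        )
        np.testing.assert_allclose(mccs, 1.0)
        np.testing.assert_allclose(aucs, 1.0)

    def test_determinism(self):
        data = separable_dataset(seed=3)
        a = cross_validate(data, "mim", 3, "knn", n_folds=4, n_repeats=2, seed=9)
        b = cross_validate(data, "mim", 3, "knn", n_folds=4, n_repeats=2, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_permuted_labels_near_zero(self):
        rng = np.random.default_rng(21)
        cfg = SyntheticConfig(
            n_early=40, n_advanced=40, n_features=10, n_informative=3,
            effect_size=1.5, seed=2,
        )
        data, _ = generate(cfg)
        data.labels = rng.permutation(data.labels)
        mccs, _ = cross_validate(
            data, "ttest", 3, "nb", n_folds=5, n_repeats=8, seed=5
        )
        se = mccs.std(ddof=1) / np.sqrt(len(mccs))
        assert abs(mccs.mean()) <= 3 * max(se, 0.02)

    def test_subset_size_bounds(self):
        data = separable_dataset()
        with pytest.raises(ParameterError):
            cross_validate(data, "ttest", 99, "nb")

    def test_global_scope_runs(self):
        data = separable_dataset(seed=4)
        mccs, _ = cross_validate(
            data, "wrs", 3, "dt", n_folds=4, n_repeats=2, rank_scope="global", seed=3
        )
        assert mccs.shape == (2,)


def toy_grid():
    """Hand-built grid: selector 'a' dominates everywhere except one tie."""
    rows = []
    for d in ("d1", "d2"):
        for c in ("c1", "c2"):
            for s, m in (("a", 0.9), ("b", 0.5), ("frmt", 0.7)):
                rows.append(
                    dict(
                        dataset_id=d, classifier=c, selector=s, subset_size=10,
                        mcc_mean=m, mcc_se=0.01, auc_mean=m, auc_se=0.01,
                        n_repeats=3, n_folds=5, seed=0,
                    )
                )
    return pd.DataFrame(rows)


class TestWinningFrequency:
    def test_dominant_selector_takes_all(self):
        wf = winning_frequency(toy_grid(), metric="mcc", group_by="overall")
        by = wf.set_index("selector")
        assert by.loc["a", "percent"] == 100.0
        assert by.loc["b", "percent"] == 0.0
        assert wf["percent"].sum() == pytest.approx(100.0)

    def test_exact_tie_splits_fractionally(self):
        grid = toy_grid()
        mask = (
            (grid.dataset_id == "d1") & (grid.classifier == "c1") & (grid.selector == "b")
        )
        grid.loc[mask, "mcc_mean"] = 0.9  # tie with 'a' in one state
        wf = winning_frequency(grid, metric="mcc", group_by="overall")
        by = wf.set_index("selector")
        assert by.loc["a", "wins"] == 3.5
        assert by.loc["b", "wins"] == 0.5
        assert wf["percent"].sum() == pytest.approx(100.0)

    def test_grouping_by_dataset(self):
        wf = winning_frequency(toy_grid(), metric="auc", group_by="dataset")
        assert set(wf["group"]) == {"d1", "d2"}
        for _, block in wf.groupby("group"):
            assert block["percent"].sum() == pytest.approx(100.0)

    def test_incomplete_grid_rejected(self):
        grid = toy_grid().iloc[:-1]
        with pytest.raises(CoverageError):
            winning_frequency(grid, metric="mcc", group_by="overall")

    def test_states_count(self):
        wf = winning_frequency(toy_grid(), metric="mcc", group_by="overall")
        assert wf["n_states"].iloc[0] == 4  # 2 datasets x 2 classifiers


class TestBestMethodSummary:
    def test_two_roles_per_dataset(self):
        summary = best_method_summary(toy_grid())
        assert len(summary) == 4  # 2 datasets x (reference, best_other)
        ref = summary[summary.role == "reference"]
        assert set(ref["selector"]) == {"frmt"}
        other = summary[summary.role == "best_other"]
        assert set(other["selector"]) == {"a"}

    def test_mean_pm_se_formatting(self):
        summary = best_method_summary(toy_grid())
        assert summary["mcc"].str.match(r"^\d+\.\d{4}±\d+\.\d{4}$").all()

    def test_single_cell_grid_reduces_to_two_rows(self):
        grid = toy_grid()
        grid = grid[(grid.dataset_id == "d1") & (grid.classifier == "c1")]
        summary = best_method_summary(grid)
        assert len(summary) == 2


class TestGridShape:
    def test_every_cell_present(self):
        data = separable_dataset(seed=8)
        grid = run_evaluation_grid(
            datasets=[("d1", data)],
            classifier_names=["nb", "knn"],
            selector_names=["ttest", "mim"],
            subset_sizes=[2, 3],
            n_folds=4,
            n_repeats=2,
            seed=0,
        )
        assert len(grid) == 8
        assert set(grid.columns) >= {
            "dataset_id", "classifier", "selector", "subset_size",
            "mcc_mean", "mcc_se", "auc_mean", "auc_se",
        }
        assert (grid.n_repeats == 2).all()
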