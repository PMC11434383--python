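"""Stratified CV, confusion-matrix metrics, ROC/PR, independent-set rates."""

import numpy as np
import pandas as pd
import pytest

from conftest import concordant_pair_auc
from pirnaml import (ClassifierSpec, ConfusionMatrix, DataError,
                     benchmark_dataset, cross_validate,
                     external_positive_rate, fit_nb, metrics_from_confusion,
                     roc_and_pr, stratified_folds)

NB = ClassifierSpec("nb_multinomial", {"alpha": 1.0}, seed=1)


class TestStratifiedFolds:
    def test_training_scale_13_13_over_10_folds(self):
        labels = ["selected"] * 13 + ["random"] * 13
        folds = stratified_folds(labels, k=10, seed=1)
        sizes = np.bincount(folds, minlength=10)
        assert set(sizes) <= {2, 3}
        for cls in ("selected", "random"):
            mask = np.array(labels) == cls
            per_fold = np.bincount(folds[mask], minlength=10)
            assert per_fold.max() - per_fold.min() <= 1

    def test_leave_one_out(self):
        labels = ["selected"] * 3 + ["random"] * 3
        folds = stratified_folds(labels, k=6, seed=1)
        assert sorted(folds) == list(range(6))

    def test_same_seed_identical(self):
        labels = ["selected"] * 9 + ["random"] * 7
        a = stratified_folds(labels, k=4, seed=3)
        b = stratified_folds(labels, k=4, seed=3)
        assert np.array_equal(a, b)

    def test_k_larger_than_n(self):
        with pytest.raises(DataError):
            stratified_folds(["selected", "random"], k=3, seed=1)


class TestMetrics:
    def test_perfect_prediction(self):
        cm = ConfusionMatrix(((7, 0), (0, 7)))
        m = metrics_from_confusion(cm)
        assert m["tpr"] == 1.0 and m["fpr"] == 0.0 and m["mcc"] == 1.0
        assert m["undefined"] == []

    def test_symmetric_one_error_each_way(self):
        m = metrics_from_confusion(ConfusionMatrix(((6, 1), (1, 6))))
        assert m["tpr"] == pytest.approx(6 / 7)
        assert m["fpr"] == pytest.approx(1 / 7)
        assert m["mcc"] == pytest.approx(35 / 49)  # (36-1)/sqrt(7^4)

    def test_everything_predicted_positive(self):
        m = metrics_from_confusion(ConfusionMatrix(((5, 0), (5, 0))))
        assert m["precision"] == 0.5 and m["fpr"] == 1.0 and m["mcc"] == 0.0
        assert "mcc" in m["undefined"]

    def test_recall_equals_tpr_and_f_is_harmonic_mean(self):
        m = metrics_from_confusion(ConfusionMatrix(((8, 2), (3, 7))))
        assert m["recall"] == m["tpr"]
        p, r = m["precision"], m["recall"]
        assert m["f_measure"] == pytest.approx(2 * p * r / (p + r))

    def test_weighted_average_between_class_values(self):
        m = metrics_from_confusion(ConfusionMatrix(((8, 2), (3, 7))))
        per = m["per_class"]
        for key in ("tpr", "precision", "f_measure"):
            lo = min(per["selected"][key], per["random"][key])
            hi = max(per["selected"][key], per["random"][key])
            assert lo - 1e-12 <= m["weighted"][key] <= hi + 1e-12

    def test_mcc_symmetric_under_class_swap(self, rng):
        for _ in range(20):
            tp, fn, fp, tn = rng.integers(0, 10, size=4)
            if (tp + fn + fp + tn) == 0:
                continue
            m1 = metrics_from_confusion(ConfusionMatrix(((tp, fn), (fp, tn))))
            m2 = metrics_from_confusion(ConfusionMatrix(((tn, fp), (fn, tp))))
            assert m1["mcc"] == pytest.approx(m2["mcc"])

    def test_empty_matrix_rejected(self):
        with pytest.raises(DataError):
            metrics_from_confusion(ConfusionMatrix(((0, 0), (0, 0))))


class TestROCandPR:
    def test_perfectly_ordered_scores(self):
        roc, pr = roc_and_pr([0.9, 0.8, 0.2, 0.1],
                             ["selected", "selected", "random", "random"])
        assert roc.auc == 1.0
        assert pr.auprc == pytest.approx(1.0)
        assert roc.points[0] == (0.0, 0.0) and roc.points[-1] == (1.0, 1.0)

    def test_all_scores_tied_gives_half(self):
        roc, _ = roc_and_pr([0.5] * 6,
                            ["selected", "random"] * 3)
        assert roc.auc == pytest.approx(0.5)

    def test_worked_three_of_four_concordant(self):
        roc, _ = roc_and_pr([0.9, 0.8, 0.4, 0.3],
                            ["selected", "random", "selected", "random"])
        assert roc.auc == pytest.approx(0.75)

    def test_auc_equals_concordant_pair_fraction(self, rng):
        """Trapezoid AUC == Mann-Whitney statistic on small datasets."""
        for _ in range(30):
            n = int(rng.integers(4, 13))
            labels = rng.choice(["selected", "random"], size=n)
            if len(set(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            roc, _ = roc_and_pr(scores, labels)
            assert roc.auc == pytest.approx(
                concordant_pair_auc(scores, labels), abs=1e-12)

    def test_monotone_fpr(self, rng):
        labels = ["selected"] * 5 + ["random"] * 5
        roc, _ = roc_and_pr(rng.random(10), labels)
        fprs = [p[0] for p in roc.points]
        assert all(a <= b for a, b in zip(fprs, fprs[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_and_pr([0.1, 0.9], ["selected", "selected"])


class TestCrossValidate:
    def test_separable_preset_is_perfect(self):
        report = cross_validate(benchmark_dataset("separable"), NB,
                                k=10, seed=1)
        assert report.accuracy == 1.0
        assert report.metrics["mcc"] == 1.0

    def test_label_permutation_near_chance(self):
        """Shuffled labels: pooled accuracy within binomial bounds at n=100."""
        from pirnaml.synthetic import GeneratorConfig, generate
        from pirnaml import build_schema, featurize_all

        table = featurize_all(
            generate(GeneratorConfig(n_per_class=50, seed=5)), build_schema())
        shuffled = table.copy()
        shuffled["label"] = np.random.default_rng(5).permutation(
            table["label"].to_numpy())
        report = cross_validate(shuffled, NB, k=10, seed=1)
        assert 0.35 <= report.accuracy <= 0.65

    def test_bitwise_reproducible(self):
        table = benchmark_dataset("paper_like")
        r1 = cross_validate(table, NB, k=10, seed=2)
        r2 = cross_validate(table, NB, k=10, seed=2)
        assert r1.confusion == r2.confusion
        assert np.array_equal(r1.scores, r2.scores)
        assert r1.to_dict() == r2.to_dict()

    def test_confusion_marginals_match_class_counts(self):
        table = benchmark_dataset("paper_like")
        report = cross_validate(table, NB, k=10, seed=1)
        cm = report.confusion
        assert cm.tp + cm.fn == 13  # actual positives
        assert cm.fp + cm.tn == 13
        assert cm.total == 26

    def test_report_serializes(self):
        report = cross_validate(benchmark_dataset("separable"), NB, k=5, seed=1)
        d = report.to_dict()
        assert d["folds"] == 5 and d["seed"] == 1
        assert d["classifier"]["name"] == "nb_multinomial"
        assert "auc" in d and "auprc" in d


class TestExternalPositiveRate:
    def test_rate_is_predicted_positive_fraction(self, toy_table):
        res = fit_nb(toy_table)
        hits = pd.DataFrame({"m1": [5.0] * 6, "m2": [0.0] * 6})
        misses = pd.DataFrame({"m1": [0.0] * 3, "m2": [5.0] * 3})
        assert external_positive_rate(res, hits) == 1.0
        assert external_positive_rate(res, misses) == 0.0
        mixed = pd.concat([hits, misses], ignore_index=True)
        assert external_positive_rate(res, mixed) == pytest.approx(6 / 9)

    def test_label_column_ignored_if_present(self, toy_table):
        res = fit_nb(toy_table)
        X = pd.DataFrame({"m1": [5.0], "m2": [0.0], "label": ["unknown"]})
        assert external_positive_rate(res, X) == 1.0


def test_plotting_draws_curves_and_bars(tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    from pirnaml.plotting import plot_pr, plot_rates, plot_roc

    report = cross_validate(benchmark_dataset("separable"), NB, k=5, seed=1)
    ax = plot_roc(report)
    assert ax.get_xlabel() == "false positive rate"
    ax2 = plot_pr(report)
    assert ax2.get_ylabel() == "precision"
    ax3 = plot_rates({"cv": report.accuracy, "null": 0.5})
    assert len(ax3.patches) == 2
    ax.figure.savefig(tmp_path / "roc.png")
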