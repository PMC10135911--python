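import numpy as np
import pytest

import momentgrn as mg
from momentgrn.evaluation import (
    EvaluationError,
    _rates_at_thresholds,
    auc_trapezoid,
)


class TestPointMetrics:
    def test_perfect_predictions(self):
        acc0, acc1 = mg.class_accuracies([0, 0, 1, 1], [0, 0, 1, 1])
        assert (acc0, acc1) == (100.0, 100.0)

    def test_hand_counts(self):
        acc0, acc1 = mg.class_accuracies([0, 0, 1, 1], [0, 1, 1, 1])
        assert (acc0, acc1) == (50.0, 100.0)

    def test_all_ones_predictor(self):
        acc0, acc1 = mg.class_accuracies([0, 1, 0, 1], [1, 1, 1, 1])
        assert (acc0, acc1) == (0.0, 100.0)

    def test_missing_class_errors(self):
        with pytest.raises(EvaluationError):
            mg.class_accuracies([1, 1], [1, 1])

    def test_recall_precision_hand_counts(self):
        assert mg.recall_precision([1, 1, 0], [1, 0, 0]) == (50.0, 100.0)
        assert mg.recall_precision([1, 0], [1, 0]) == (100.0, 100.0)

    def test_no_positive_predictions(self):
        rec, prec = mg.recall_precision([1, 0], [0, 0])
        assert rec == 0.0
        assert np.isnan(prec)


class TestROC:
    def test_perfect_and_anti_perfect(self):
        labels = np.array([0, 0, 1, 1, 0, 1])
        _, auc = mg.roc_with_error(labels, labels.astype(float), n_resamples=50, seed=0)
        assert auc == pytest.approx(1.0, abs=1e-12)
        _, auc = mg.roc_with_error(
            labels, 1.0 - labels.astype(float), n_resamples=50, seed=0
        )
        assert auc == pytest.approx(0.0, abs=1e-12)

    def test_random_scores_match_mann_whitney(self):
        rng = np.random.default_rng(100)
        labels = np.repeat([0, 1], 500)
        scores = rng.random(1000)
        curve, auc = mg.roc_with_error(labels, scores, n_resamples=200, seed=1)
        assert 0.45 <= auc <= 0.55
        # brute-force concordance count
        pos, neg = scores[labels == 1], scores[labels == 0]
        conc = np.mean(pos[:, None] > neg[None, :]) + 0.5 * np.mean(
            pos[:, None] == neg[None, :]
        )
        assert auc == pytest.approx(conc, abs=0.01)

    def test_informative_scores_match_mann_whitney(self):
        rng = np.random.default_rng(101)
        labels = np.repeat([0, 1], 400)
        scores = np.concatenate([rng.normal(0, 1, 400), rng.normal(1, 1, 400)])
        _, auc = mg.roc_with_error(labels, scores, n_resamples=200, seed=2)
        pos, neg = scores[labels == 1], scores[labels == 0]
        conc = np.mean(pos[:, None] > neg[None, :])
        assert auc == pytest.approx(conc, abs=0.01)

    def test_curve_in_unit_square_and_monotone(self):
        rng = np.random.default_rng(102)
        labels = np.repeat([0, 1], 100)
        scores = rng.random(200) + labels
        curve, _ = mg.roc_with_error(labels, scores, n_resamples=100, seed=3)
        for arr in (curve.x_mean, curve.y_mean):
            assert np.all((arr >= 0) & (arr <= 1))
        order = np.argsort(curve.x_mean, kind="stable")
        # TPR decreases as the threshold rises; sorted by FPR it must rise
        tpr_sorted = curve.y_mean[np.lexsort((curve.y_mean, curve.x_mean))]
        assert np.all(np.diff(tpr_sorted) >= -1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            mg.roc_with_error(np.ones(5, int), np.random.rand(5))

    def test_bootstrap_sd_shrinks_with_sample_size(self):
        rng = np.random.default_rng(103)
        sds = []
        for n in (100, 400, 1600):
            labels = np.repeat([0, 1], n // 2)
            scores = np.concatenate(
                [rng.normal(0, 1, n // 2), rng.normal(1, 1, n // 2)]
            )
            curve, _ = mg.roc_with_error(labels, scores, n_resamples=300, seed=4)
            mid = len(curve.thresholds) // 2
            sds.append(curve.y_sd[mid])
        assert sds[0] > sds[1] > sds[2]
        assert sds[0] / sds[2] > 2.0  # ~sqrt(16) ideally, loose bound


class TestPR:
    def test_perfect_scores_give_unit_precision(self):
        labels = np.repeat([0, 1], 20)
        curve = mg.pr_with_error(labels, labels.astype(float), n_resamples=50, seed=0)
        # thresholds above the highest negative score select only positives
        selective = (curve.thresholds > 0) & (curve.x_mean > 0)
        assert selective.any()
        np.testing.assert_allclose(curve.y_mean[selective], 1.0)

    def test_constant_scores_recall_one_at_prevalence(self):
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        curve = mg.pr_with_error(labels, np.ones(8), n_resamples=400, seed=1)
        # all thresholds <= the constant predict everything positive
        assert curve.x_mean[0] == pytest.approx(1.0)
        assert curve.y_mean[0] == pytest.approx(labels.mean(), abs=0.05)

    def test_hand_worked_example(self):
        """Deterministic rates at explicit thresholds on six points."""
        labels = np.array([1, 0, 1, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.2])
        thr = np.array([0.5, 0.65, 0.75, 0.85, 0.95])
        tpr, fpr, prec = _rates_at_thresholds(labels, scores, thr)
        np.testing.assert_allclose(tpr, [1.0, 2 / 3, 1 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(fpr, [1 / 3, 1 / 3, 1 / 3, 0.0, 0.0])
        np.testing.assert_allclose(prec[:4], [3 / 4, 2 / 3, 1 / 2, 1.0])
        assert np.isnan(prec[4])


class TestNetworkComparison:
    def test_all_shared_validated(self):
        gold = mg.GoldStandard(edges=frozenset({("T", "a"), ("T", "b")}))
        comp = mg.compare_networks(set(gold.edges), set(gold.edges), gold, "T")
        assert comp.shared_validated == set(gold.edges)
        assert not (comp.shared_unvalidated | comp.unique_a | comp.unique_b)

    def test_disjoint_predictions(self):
        gold = mg.GoldStandard(edges=frozenset({("T", "x")}))
        a = {("T", "p")}
        b = {("T", "q")}
        comp = mg.compare_networks(a, b, gold, "T")
        assert comp.shared_validated == set() and comp.shared_unvalidated == set()
        assert comp.unique_a == a and comp.unique_b == b

    def test_set_arithmetic_example(self):
        e1, e2, e3, e4 = ("T", "1"), ("T", "2"), ("T", "3"), ("T", "4")
        gold = mg.GoldStandard(edges=frozenset({e2}))
        comp = mg.compare_networks({e1, e2, e3}, {e2, e3, e4}, gold, "T")
        assert comp.shared_validated == {e2}
        assert comp.shared_unvalidated == {e3}
        assert comp.unique_a == {e1}
        assert comp.unique_b == {e4}

    def test_categories_partition_union(self):
        rng = np.random.default_rng(9)
        targets = [f"t{i}" for i in range(30)]
        a = {("T", t) for t in rng.choice(targets, 12, replace=False)}
        b = {("T", t) for t in rng.choice(targets, 12, replace=False)}
        gold = mg.GoldStandard(
            edges=frozenset({("T", t) for t in rng.choice(targets, 10, replace=False)})
        )
        comp = mg.compare_networks(a, b, gold, "T")
        cats = [getattr(comp, name) for name in comp.CATEGORIES]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not (cats[i] & cats[j])
        assert set().union(*cats) == a | b


class TestExport:
    def test_tsv_round_trip(self, tmp_path):
        e1, e2, e3, e4 = ("T", "1"), ("T", "2"), ("T", "3"), ("T", "4")
        gold = mg.GoldStandard(edges=frozenset({e2}))
        comp = mg.compare_networks({e1, e2, e3}, {e2, e3, e4}, gold, "T")
        path = tmp_path / "net.tsv"
        mg.export_network(comp, path, format="TSV")
        frame = mg.evaluation.read_network(path)
        assert len(frame) == 4
        cats = dict(zip(frame["target"].astype(str), frame["category"]))
        assert cats["2"] == "shared_validated"
        assert cats["1"] == "unique_a"

    def test_sif_line_count(self, tmp_path):
        gold = mg.GoldStandard(edges=frozenset({("T", "a")}))
        comp = mg.compare_networks(
            {("T", "a"), ("T", "b")}, {("T", "a"), ("T", "c")}, gold, "T"
        )
        path = tmp_path / "net.sif"
        mg.export_network(comp, path, format="SIF")
        assert len(path.read_text().strip().splitlines()) == 3

    def test_empty_comparison_writes_header(self, tmp_path):
        gold = mg.GoldStandard(edges=frozenset({("T", "a")}))
        comp = mg.compare_networks(set(), set(), gold, "T")
        path = tmp_path / "empty.tsv"
        mg.export_network(comp, path, format="TSV")
        assert path.read_text().startswith("regulator\ttarget\tcategory")


def test_auc_trapezoid_degenerate_order():
    # vertical segments contribute no area
    fpr = np.array([0.0, 1.0, 1.0])
    tpr = np.array([0.0, 0.0, 1.0])
    assert auc_trapezoid(fpr, tpr) == pytest.approx(0.0)
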