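"""Metric suite: confusion counts, ratio metrics, trapezoid AUCs, bootstrap.

Oracles: a naive per-pixel counting loop for the confusion matrix,
Mann–Whitney pair counting for AUC-ROC, exhaustive threshold enumeration
for AUC-PR, and scikit-learn as an independent library cross-check.
"""

import numpy as np
import pytest

import retinaug as ra
from retinaug.labels import FULL9, LabelMap
from retinaug.losses import ScoreMap
from retinaug.metrics import basic_metrics


def _random_labelmap(rng, h, w, schema=FULL9):
    return LabelMap(rng.integers(0, schema.n_classes, size=(h, w)), schema)


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self, rng):
        truth = _random_labelmap(rng, 10, 10)
        cm = ra.confusion_matrix(truth, truth)
        assert np.trace(cm.counts) == cm.total == 100
        assert (cm.counts == np.diag(np.diag(cm.counts))).all()

    def test_swapped_binary_maps_are_antidiagonal(self):
        schema = ra.ClassSchema("bin", ("background", "fg"))
        a = LabelMap(np.array([[0, 1], [0, 1]]), schema)
        b = LabelMap(np.array([[1, 0], [1, 0]]), schema)
        cm = ra.confusion_matrix(b, a)
        assert cm.counts[0, 0] == cm.counts[1, 1] == 0
        assert cm.counts[0, 1] == cm.counts[1, 0] == 2

    def test_matches_naive_counting_loop(self, rng):
        pred = _random_labelmap(rng, 9, 7)
        truth = _random_labelmap(rng, 9, 7)
        cm = ra.confusion_matrix(pred, truth)
        expected = np.zeros((9, 9), dtype=int)
        for i in range(9):
            for j in range(7):
                expected[truth.grid[i, j], pred.grid[i, j]] += 1
        assert np.array_equal(cm.counts, expected)

    def test_marginals_conserve_pixels_and_ovr_tp_sums_to_trace(self, rng):
        pred = _random_labelmap(rng, 8, 8)
        truth = _random_labelmap(rng, 8, 8)
        cm = ra.confusion_matrix(pred, truth)
        assert cm.counts.sum() == 64
        tp_sum = sum(cm.one_vs_rest(c)[0] for c in range(9))
        assert tp_sum == np.trace(cm.counts)

    def test_schema_mismatch_rejected(self, rng):
        a = _random_labelmap(rng, 4, 4, FULL9)
        b = _random_labelmap(rng, 4, 4, ra.ANAT5)
        with pytest.raises(ValueError):
            ra.confusion_matrix(a, b)


class TestBasicMetrics:
    def test_printed_count_example(self):
        # TP=3, FP=1, FN=2, TN=10 in a binary one-vs-rest layout
        schema = ra.ClassSchema("bin", ("background", "fg"))
        counts = np.array([[10, 1], [2, 3]])
        per_class, flags = basic_metrics(ra.ConfusionMatrix(counts, schema))
        fg = per_class["fg"]
        assert fg["precision"] == pytest.approx(0.75)
        assert fg["recall"] == pytest.approx(0.6)
        assert fg["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)
        assert fg["iou"] == pytest.approx(0.5)
        assert fg["accuracy"] == pytest.approx(13 / 16)
        assert not flags

    def test_perfect_prediction_gives_all_ones(self, rng):
        truth = _random_labelmap(rng, 12, 12)
        cm = ra.confusion_matrix(truth, truth)
        per_class, _ = basic_metrics(cm)
        for cname in FULL9.classes:
            if (truth.grid == FULL9.id_of(cname)).any():
                assert all(v == 1.0 for v in per_class[cname].values()), cname

    def test_empty_unpredicted_class_is_zero_and_flagged(self):
        schema = ra.ClassSchema("bin", ("background", "fg"))
        counts = np.array([[10, 0], [0, 0]])  # class fg absent and never predicted
        per_class, flags = basic_metrics(ra.ConfusionMatrix(counts, schema))
        fg = per_class["fg"]
        assert fg["iou"] == fg["precision"] == fg["recall"] == fg["f1"] == 0.0
        assert fg["accuracy"] == 1.0
        assert set(flags["fg"]) == {"iou", "precision", "recall", "f1"}


def mann_whitney_auc(scores, truth):
    pos = scores[truth]
    neg = scores[~truth]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_is_one(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truth = np.array([True, True, False, False])
        _, auc = ra.roc_auc(scores, truth)
        assert auc == 1.0

    def test_half_concordant_pairs_give_half(self):
        scores = np.array([0.9, 0.1, 0.6, 0.4])
        truth = np.array([True, True, False, False])
        _, auc = ra.roc_auc(scores, truth)
        assert auc == pytest.approx(0.5)  # 2 of 4 pairs concordant

    def test_matches_mann_whitney_on_tie_free_scores(self, rng):
        for _ in range(10):
            scores = rng.permutation(np.linspace(0.01, 0.99, 300))
            truth = rng.uniform(size=300) < 0.15
            if truth.sum() in (0, 300):
                continue
            _, auc = ra.roc_auc(scores, truth)
            assert abs(auc - mann_whitney_auc(scores, truth)) <= 1e-12

    def test_matches_sklearn_with_ties(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.integers(0, 10, size=500) / 10.0  # heavy ties
        truth = rng.uniform(size=500) < 0.3
        _, auc = ra.roc_auc(scores, truth)
        assert auc == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.uniform(size=200)
        truth = rng.uniform(size=200) < 0.4
        _, a = ra.roc_auc(scores, truth)
        _, b = ra.roc_auc(np.exp(3 * scores), truth)
        assert a == pytest.approx(b, abs=1e-12)

    def test_negated_scores_complement_to_one(self, rng):
        scores = rng.permutation(np.linspace(0, 1, 100))
        truth = rng.uniform(size=100) < 0.5
        _, a = ra.roc_auc(scores, truth)
        _, b = ra.roc_auc(-scores, truth)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_curve_endpoints_and_ordering(self, rng):
        scores = rng.uniform(size=64)
        truth = rng.uniform(size=64) < 0.25
        curve, _ = ra.roc_auc(scores, truth)
        assert curve.x[0] == 0.0 and curve.y[0] == 0.0
        assert curve.x[-1] == 1.0 and curve.y[-1] == 1.0
        assert (np.diff(curve.x) >= 0).all()

    def test_single_class_truth_is_an_error(self):
        with pytest.raises(ValueError):
            ra.roc_auc(np.array([0.1, 0.2]), np.array([True, True]))


def enumerate_pr_auc(scores, truth):
    """Exhaustive threshold enumeration accumulating the PR trapezoids."""
    thresholds = np.unique(scores)[::-1]
    pts = []
    P = truth.sum()
    for t in thresholds:
        sel = scores >= t
        tp = (sel & truth).sum()
        prec = tp / sel.sum()
        rec = tp / P
        pts.append((rec, prec))
    auc, (r_prev, p_prev) = 0.0, (0.0, pts[0][1])
    for r, p in pts:
        auc += (r - r_prev) * (p + p_prev) / 2.0
        r_prev, p_prev = r, p
    return auc


class TestPrAuc:
    def test_perfect_separation_is_one(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truth = np.array([True, True, False, False])
        _, auc = ra.pr_auc(scores, truth)
        assert auc == 1.0

    def test_three_point_enumeration_example(self):
        scores = np.array([0.9, 0.8, 0.7])
        truth = np.array([True, False, True])
        _, auc = ra.pr_auc(scores, truth)
        assert auc == pytest.approx(enumerate_pr_auc(scores, truth), abs=1e-12)
        # hand check: thresholds 0.9/0.8/0.7 → (r,P) = (.5,1), (.5,.5), (1,2/3)
        assert auc == pytest.approx(0.5 * 1.0 + 0.5 * (0.5 + 2 / 3) / 2, abs=1e-12)

    def test_matches_enumeration_on_random_scores(self, rng):
        for _ in range(10):
            scores = rng.uniform(size=150)
            truth = rng.uniform(size=150) < 0.2
            if truth.sum() == 0:
                continue
            _, auc = ra.pr_auc(scores, truth)
            assert auc == pytest.approx(enumerate_pr_auc(scores, truth), abs=1e-12)

    def test_all_positive_truth_gives_unit_precision_curve(self):
        scores = np.array([0.3, 0.6, 0.9])
        truth = np.array([True, True, True])
        curve, auc = ra.pr_auc(scores, truth)
        assert (curve.y == 1.0).all()
        assert auc == 1.0

    def test_no_positives_is_an_error(self):
        with pytest.raises(ValueError):
            ra.pr_auc(np.array([0.1, 0.9]), np.array([False, False]))


class TestBootstrap:
    def test_constant_values_give_degenerate_interval(self):
        lo, hi = ra.bootstrap_ci([0.7] * 10, n_boot=200, seed=1)
        assert lo == hi == 0.7

    def test_fixed_seed_reproducible(self, rng):
        vals = rng.normal(size=30).tolist()
        assert ra.bootstrap_ci(vals, seed=5) == ra.bootstrap_ci(vals, seed=5)

    def test_interval_covers_true_mean_about_95_percent(self):
        """Coverage simulation at reduced scale: N(0,1), n=100 per replicate."""
        rng = np.random.default_rng(77)
        hits = 0
        reps = 120
        for _ in range(reps):
            vals = rng.normal(size=100)
            lo, hi = ra.bootstrap_ci(vals, n_boot=500, seed=rng)
            hits += lo <= 0.0 <= hi
        assert 0.88 <= hits / reps <= 1.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ra.bootstrap_ci([1.0])


class TestEvaluate:
    def test_perfect_simplex_prediction_scores_one_everywhere(self, clean_phantom):
        scores = ScoreMap(ra.one_hot(clean_phantom.labels))
        report = ra.evaluate(scores, clean_phantom.labels)
        for m, v in report.lesion_mean.items():
            assert v == 1.0, m
        for m, v in report.all_class_mean.items():
            assert v == 1.0, m

    def test_report_consistent_with_individual_calls(self, clean_phantom, rng):
        noise = rng.dirichlet(np.ones(9), size=clean_phantom.labels.shape)
        soft = 0.7 * ra.one_hot(clean_phantom.labels) + 0.3 * noise
        scores = ScoreMap(soft)
        report = ra.evaluate(scores, clean_phantom.labels)
        cm = ra.confusion_matrix(
            scores.argmax_labels(FULL9), clean_phantom.labels
        )
        per_class, _ = basic_metrics(cm)
        for cname in FULL9.classes:
            for m in ("accuracy", "iou", "precision", "recall", "f1"):
                assert report.per_class[cname][m] == per_class[cname][m]
        mask = clean_phantom.labels.mask_of("HE")
        _, auc = ra.roc_auc(scores.tensor[:, :, FULL9.id_of("HE")], mask)
        assert report.per_class["HE"]["auc_roc"] == auc

    def test_corrupted_class_recall_tracks_error_rate(self, clean_phantom, rng):
        """Flip a known fraction e of retina pixels to background; recall of
        retina must equal 1 − e exactly (corruption is constructed)."""
        e = 0.2
        labels = clean_phantom.labels
        pred_grid = labels.grid.copy()
        retina_idx = np.flatnonzero(labels.grid.ravel() == FULL9.id_of("retina"))
        n_flip = int(round(e * retina_idx.size))
        flip = rng.choice(retina_idx, size=n_flip, replace=False)
        pred_flat = pred_grid.ravel()
        pred_flat[flip] = 0
        pred = LabelMap(pred_flat.reshape(labels.shape), FULL9)
        scores = ScoreMap(ra.one_hot(pred))
        report = ra.evaluate(scores, labels)
        expected_recall = 1 - n_flip / retina_idx.size
        assert report.per_class["retina"]["recall"] == pytest.approx(
            expected_recall, abs=1e-12
        )

    def test_all_values_lie_in_unit_interval(self, noisy_phantom, rng):
        noise = rng.dirichlet(np.ones(9), size=noisy_phantom.labels.shape)
        scores = ScoreMap(0.5 * ra.one_hot(noisy_phantom.labels) + 0.5 * noise)
        report = ra.evaluate(scores, noisy_phantom.labels)
        for cname, metrics_ in report.per_class.items():
            for m, v in metrics_.items():
                assert 0.0 <= v <= 1.0, (cname, m)
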