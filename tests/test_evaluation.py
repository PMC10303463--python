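"""Pixel and finding-level metrics: ROC, Dice/Jaccard, component matching,
FROC, against brute-force oracles."""

import numpy as np
import pytest

from steersim.errors import AlignmentError, UndefinedMetricError
from steersim.evaluation import (argmax_class_map,
                                 extract_findings, froc, match_findings,
                                 overlap_metrics, pooled_roc)
from steersim.ground_truth import RiskMap
from steersim.segmentation import ProbabilityMap


def _prob_map(p3):
    p3 = np.asarray(p3, dtype=float)
    probs = np.zeros((*p3.shape, 4))
    probs[..., 3] = p3
    probs[..., 0] = 1.0 - p3
    return ProbabilityMap(probs=probs)


def _risk(labels):
    return RiskMap(labels=np.asarray(labels, dtype=np.uint8),
                   alignment={"grid": "toy"})


def mann_whitney_auc(scores, labels):
    """Exhaustive pair counting: P(score+ > score-) + 0.5 P(tie)."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for p in pos:
        wins += np.sum(p > neg)
        ties += np.sum(p == neg)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestPooledROC:
    def test_perfect_separation(self):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[2:5, 2:5] = 3
        pm = _prob_map((labels == 3).astype(float))
        r = pooled_roc([pm], [_risk(labels)], 3)
        assert r.auc == pytest.approx(1.0)
        assert r.operating_point["TPR"] == pytest.approx(1.0)
        assert r.operating_point["TNR"] == pytest.approx(1.0)

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(0)
        n = 100_000
        scores = rng.random(n)
        labels = (rng.random(n) < 0.3).astype(np.uint8) * 3
        pm = _prob_map(scores.reshape(1, -1))
        r = pooled_roc([pm], [_risk(labels.reshape(1, -1))], 3)
        assert r.auc == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 600
        scores = rng.choice(np.linspace(0, 1, 21), size=n)  # with ties
        labels = (rng.random(n) < 0.25).astype(np.uint8) * 3
        pm = _prob_map(scores.reshape(1, -1))
        r = pooled_roc([pm], [_risk(labels.reshape(1, -1))], 3)
        oracle = mann_whitney_auc(scores, labels == 3)
        assert r.auc == pytest.approx(oracle, abs=1e-12)

    def test_absent_class_raises(self):
        pm = _prob_map(np.zeros((4, 4)))
        with pytest.raises(UndefinedMetricError):
            pooled_roc([pm], [_risk(np.zeros((4, 4)))], 3)


class TestOverlapMetrics:
    def test_identical_maps(self):
        labels = np.tile(np.arange(4, dtype=np.uint8), (8, 2))
        out = overlap_metrics(labels, _risk(labels))
        for c in range(4):
            assert out[c]["dice"] == 1.0 and out[c]["jaccard"] == 1.0

    def test_disjoint_class(self):
        pred = np.zeros((4, 4), dtype=np.uint8)
        pred[0, 0] = 3
        truth = np.zeros((4, 4), dtype=np.uint8)
        truth[3, 3] = 3
        out = overlap_metrics(pred, _risk(truth))
        assert out[3]["dice"] == 0.0 and out[3]["jaccard"] == 0.0

    def test_hand_computed_counts(self):
        # |P| = 30, |G| = 50, |P ∩ G| = 20 for class 3
        pred = np.zeros((10, 10), dtype=np.uint8)
        truth = np.zeros((10, 10), dtype=np.uint8)
        pred.ravel()[0:30] = 3
        truth.ravel()[10:60] = 3
        out = overlap_metrics(pred, _risk(truth))
        assert out[3]["dice"] == pytest.approx(0.5)
        assert out[3]["jaccard"] == pytest.approx(1 / 3)

    def test_jaccard_dice_identity(self):
        rng = np.random.default_rng(1)
        pred = rng.integers(0, 4, size=(50, 50)).astype(np.uint8)
        truth = rng.integers(0, 4, size=(50, 50)).astype(np.uint8)
        out = overlap_metrics(pred, _risk(truth))
        for c in range(4):
            d, j = out[c]["dice"], out[c]["jaccard"]
            assert j == pytest.approx(d / (2 - d), abs=1e-12)

    def test_absent_class_undefined(self):
        pred = np.zeros((4, 4), dtype=np.uint8)
        out = overlap_metrics(pred, _risk(np.zeros((4, 4))))
        assert out[3]["dice"] is None and "note" in out[3]

    def test_argmax_ties_break_low(self):
        probs = np.full((2, 2, 4), 0.25)
        assert np.all(argmax_class_map(ProbabilityMap(probs=probs)) == 0)


def flood_fill_count(mask):
    """8-connectivity component count by explicit flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    n = 0
    for r0, c0 in zip(*mask.nonzero()):
        if seen[r0, c0]:
            continue
        n += 1
        stack = [(r0, c0)]
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                            and mask[rr, cc] and not seen[rr, cc]):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
    return n


class TestExtractFindings:
    def test_two_disjoint_blobs(self):
        labels = np.zeros((20, 20), dtype=np.uint8)
        labels[2:5, 2:5] = 3
        labels[10:14, 10:14] = 3
        assert extract_findings(_risk(labels)).n == 2

    def test_diagonal_touch_is_one_finding(self):
        labels = np.zeros((6, 6), dtype=np.uint8)
        labels[1, 1] = 3
        labels[2, 2] = 3
        assert extract_findings(_risk(labels)).n == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((100, 100)) < 0.3
        labels = mask.astype(np.uint8) * 3
        assert extract_findings(_risk(labels)).n == flood_fill_count(mask)

    def test_threshold_required_for_probabilities(self):
        with pytest.raises(UndefinedMetricError):
            extract_findings(_prob_map(np.zeros((4, 4))))

    def test_min_area_filter(self):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[0, 0] = 3            # 1 px
        labels[5:8, 5:8] = 3        # 9 px
        fs = extract_findings(_risk(labels), min_area=2)
        assert fs.n == 1


class TestMatchFindings:
    def test_identity_prediction(self):
        labels = np.zeros((20, 20), dtype=np.uint8)
        labels[2:5, 2:5] = 3
        labels[10:14, 10:14] = 3
        truth = extract_findings(_risk(labels))
        pred = extract_findings(_prob_map((labels == 3) * 1.0), threshold=0.5)
        m = match_findings(pred, truth)
        assert (m["TP"], m["FP"], m["FN"]) == (2, 0, 0)

    def test_single_blob_covering_two_truths(self):
        truth_labels = np.zeros((10, 20), dtype=np.uint8)
        truth_labels[2:5, 2:6] = 3
        truth_labels[2:5, 12:16] = 3
        pred3 = np.zeros((10, 20))
        pred3[3, 1:18] = 0.9        # one blob spanning both truths
        truth = extract_findings(_risk(truth_labels))
        pred = extract_findings(_prob_map(pred3), threshold=0.5)
        m = match_findings(pred, truth)
        assert (m["TP"], m["FP"], m["FN"]) == (2, 0, 0)
        assert pred.statuses == ["TP"]

    def test_empty_prediction(self):
        labels = np.zeros((20, 20), dtype=np.uint8)
        labels[2:5, 2:5] = 3
        labels[10:14, 10:14] = 3
        truth = extract_findings(_risk(labels))
        pred = extract_findings(_prob_map(np.zeros((20, 20))), threshold=0.5)
        m = match_findings(pred, truth)
        assert (m["TP"], m["FP"], m["FN"]) == (0, 0, 2)

    def test_grid_mismatch_raises(self):
        a = extract_findings(_risk(np.zeros((4, 4))))
        b = extract_findings(_risk(np.zeros((5, 5))))
        with pytest.raises(AlignmentError):
            match_findings(a, b)


class TestFROC:
    def test_sweep_has_101_thresholds(self, findings_toy):
        c = froc(findings_toy["prob_maps"], findings_toy["risk_maps"])
        assert len(c.thresholds) == 101
        assert c.thresholds[0] == 1.0 and c.thresholds[-1] == 0.0

    def test_perfect_maps(self):
        labels = np.zeros((20, 20), dtype=np.uint8)
        labels[2:6, 2:6] = 3
        pm = _prob_map((labels == 3) * 1.0)
        c = froc([pm], [_risk(labels)])
        mid = (c.thresholds > 0) & (c.thresholds < 1)
        assert np.all(c.sensitivity[mid] == 1.0)
        assert np.all(c.fp_per_image[mid] == 0.0)

    def test_toy_curve_matches_exhaustive_oracle(self, findings_toy):
        c = froc(findings_toy["prob_maps"], findings_toy["risk_maps"])
        # independent oracle: per threshold, re-derive counts by flood fill
        for i, thr in enumerate(c.thresholds):
            tp = fp = 0
            for pm, rm in zip(findings_toy["prob_maps"],
                              findings_toy["risk_maps"]):
                pmask = pm.probs[..., 3] >= thr
                from scipy import ndimage
                plab, pn = ndimage.label(pmask, np.ones((3, 3)))
                tlab, tn = ndimage.label(rm.labels == 3, np.ones((3, 3)))
                for g in range(1, tn + 1):
                    if pmask[tlab == g].any():
                        tp += 1
                for f in range(1, pn + 1):
                    if not (rm.labels == 3)[plab == f].any():
                        fp += 1
            assert c.sensitivity[i] == pytest.approx(tp / c.n_truth)
            assert c.fp_per_image[i] == pytest.approx(fp / 3)

    def test_conservation_at_every_threshold(self, findings_toy):
        for thr in np.round(np.linspace(1, 0, 101), 2):
            tp = fn = 0
            for pm, rm in zip(findings_toy["prob_maps"],
                              findings_toy["risk_maps"]):
                m = match_findings(
                    extract_findings(pm, threshold=thr),
                    extract_findings(rm))
                tp += m["TP"]
                fn += m["FN"]
            assert tp + fn == findings_toy["expected"]["n_truth"]

    def test_monotone_on_toy(self, findings_toy):
        c = froc(findings_toy["prob_maps"], findings_toy["risk_maps"])
        assert np.all(np.diff(c.sensitivity) >= 0)
        assert np.all(np.diff(c.fp_per_image) >= 0)

    def test_sensitivity_interpolation(self):
        from steersim.evaluation import FROCCurve
        c = FROCCurve(thresholds=np.array([1.0, 0.5, 0.0]),
                      sensitivity=np.array([0.0, 0.5, 1.0]),
                      fp_per_image=np.array([0.0, 2.0, 6.0]),
                      n_truth=4, n_images=2)
        assert c.sensitivity_at(4.0) == pytest.approx(0.75)

    def test_no_truth_raises(self):
        pm = _prob_map(np.zeros((4, 4)))
        with pytest.raises(UndefinedMetricError):
            froc([pm], [_risk(np.zeros((4, 4)))])


class TestFindingsToyTable:
    def test_manual_overlap_table_at_half(self, findings_toy):
        tp = fp = fn = 0
        for pm, rm in zip(findings_toy["prob_maps"],
                          findings_toy["risk_maps"]):
            m = match_findings(extract_findings(pm, threshold=0.5),
                               extract_findings(rm))
            tp += m["TP"]
            fp += m["FP"]
            fn += m["FN"]
        exp = findings_toy["expected"][0.5]
        assert (tp, fp, fn) == (exp["TP"], exp["FP"], exp["FN"])
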