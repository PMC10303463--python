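"""Segmentation and lesion-detection metrics.

Pixel-level metrics pool all test pixels: one-vs-rest ROC curves with the
operating point closest to the ideal corner (FPR, TPR) = (0, 1), and Dice /
Jaccard overlap of the hard (argmax) class maps. Finding-level metrics work
on 8-connected components of the lesion class (class 3): a ground-truth
cluster is a true positive if any predicted lesion pixel overlaps it, a
false negative otherwise; a predicted component overlapping no ground-truth
cluster is one false positive. Sweeping the lesion-probability threshold
from 1.00 down to 0.00 in 0.01 steps yields the FROC curve (sensitivity vs
mean false positives per image).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import AlignmentError, UndefinedMetricError
from .ground_truth import N_RISK_CLASSES, RiskMap
from .segmentation import ProbabilityMap

LESION_CLASS = 3
_STRUCT8 = np.ones((3, 3), dtype=bool)


def _probs_of(pm) -> np.ndarray:
    return pm.probs if isinstance(pm, ProbabilityMap) else np.asarray(pm)


def _labels_of(rm) -> np.ndarray:
    return rm.labels if isinstance(rm, RiskMap) else np.asarray(rm)


# ------------------------------------------------------------------- ROC

@dataclass
class ROCCurve:
    class_id: int
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    operating_point: dict     # threshold, TPR, TNR, PPV, NPV


def pooled_roc(prob_maps, risk_maps, class_id: int) -> ROCCurve:
    """One-vs-rest ROC over all pixels pooled across images.

    AUC by the trapezoidal rule; the operating point is the curve point
    minimising the Euclidean distance to (FPR, TPR) = (0, 1), at which
    TPR/TNR/PPV/NPV are computed (score >= threshold predicts positive).
    """
    scores, labels = [], []
    for pm, rm in zip(prob_maps, risk_maps):
        p = _probs_of(pm)
        t = _labels_of(rm)
        if p.shape[:-1] != t.shape:
            raise AlignmentError("probability and risk maps do not align")
        scores.append(p[..., class_id].ravel())
        labels.append((t.ravel() == class_id))
    s = np.concatenate(scores)
    y = np.concatenate(labels)
    npos, nneg = int(y.sum()), int((~y).sum())
    if npos == 0 or nneg == 0:
        raise UndefinedMetricError(
            f"class {class_id} is absent (or universal) in the pooled labels")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    d2 = fpr ** 2 + (1.0 - tpr) ** 2
    i = int(np.argmin(d2))
    t_op = float(thr[i])
    pred = s >= t_op
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = npos - tp
    tn = nneg - fp
    op = {
        "threshold": t_op,
        "TPR": tp / npos,
        "TNR": tn / nneg,
        "PPV": tp / (tp + fp) if tp + fp else float("nan"),
        "NPV": tn / (tn + fn) if tn + fn else float("nan"),
    }
    return ROCCurve(class_id=class_id, thresholds=thr, fpr=fpr, tpr=tpr,
                    auc=auc, operating_point=op)


# --------------------------------------------------------------- overlap

def argmax_class_map(prob_map) -> np.ndarray:
    """Hard class map; ties resolve to the lowest (safest) class code."""
    return np.argmax(_probs_of(prob_map), axis=-1).astype(np.uint8)


def overlap_metrics(pred_class_maps, risk_maps,
                    n_classes: int = N_RISK_CLASSES) -> dict:
    """Pooled per-class Dice and Jaccard of hard class maps vs ground truth.

    Classes whose prediction-union-truth pixel set is empty are undefined and
    reported as such rather than as 0 or 1.
    """
    if not isinstance(pred_class_maps, (list, tuple)):
        pred_class_maps = [pred_class_maps]
        risk_maps = [risk_maps]
    inter = np.zeros(n_classes, dtype=np.int64)
    np_pred = np.zeros(n_classes, dtype=np.int64)
    np_true = np.zeros(n_classes, dtype=np.int64)
    for pred, rm in zip(pred_class_maps, risk_maps):
        pred = np.asarray(pred)
        t = _labels_of(rm)
        if pred.shape != t.shape:
            raise AlignmentError("prediction and risk map do not align")
        for c in range(n_classes):
            pc, tc = pred == c, t == c
            inter[c] += np.sum(pc & tc)
            np_pred[c] += pc.sum()
            np_true[c] += tc.sum()
    out = {}
    for c in range(n_classes):
        union = np_pred[c] + np_true[c] - inter[c]
        if union == 0:
            out[c] = {"dice": None, "jaccard": None,
                      "note": "undefined: class absent from both maps"}
        else:
            dice = 2.0 * inter[c] / (np_pred[c] + np_true[c])
            out[c] = {"dice": float(dice),
                      "jaccard": float(inter[c] / union)}
    return out


# -------------------------------------------------------------- findings

@dataclass
class FindingSet:
    """8-connected lesion-class components of one image."""

    label_image: np.ndarray          # int32, 0 = background, 1..n findings
    n: int
    source: str                      # "predicted" | "ground_truth"
    statuses: list = field(default_factory=list)   # per finding, after match

    def pixel_count(self, finding: int) -> int:
        return int(np.sum(self.label_image == finding))


def extract_findings(prob_or_label_map, threshold: float | None = None,
                     min_area: int = 1, source: str | None = None,
                     class_id: int = LESION_CLASS) -> FindingSet:
    """Connected lesion components of a probability or hard label map.

    Probability input is thresholded at ``threshold`` on the lesion-class
    channel (``>=``); label input uses ``label == class_id`` directly.
    Components are 8-connected; those smaller than ``min_area`` pixels drop.
    """
    if isinstance(prob_or_label_map, ProbabilityMap) or (
            isinstance(prob_or_label_map, np.ndarray)
            and prob_or_label_map.ndim == 3):
        if threshold is None:
            raise UndefinedMetricError(
                "a threshold is required for probability input")
        mask = _probs_of(prob_or_label_map)[..., class_id] >= threshold
        src = source or "predicted"
    else:
        mask = _labels_of(prob_or_label_map) == class_id
        src = source or "ground_truth"
    lab, n = ndimage.label(mask, structure=_STRUCT8)
    if min_area > 1 and n:
        sizes = np.bincount(lab.ravel())
        small = np.flatnonzero(sizes < min_area)
        lab[np.isin(lab, small[small > 0])] = 0
        relabel = np.zeros(n + 1, dtype=np.int32)
        kept = [i for i in range(1, n + 1) if sizes[i] >= min_area]
        for new, old in enumerate(kept, start=1):
            relabel[old] = new
        lab = relabel[lab]
        n = len(kept)
    return FindingSet(label_image=lab.astype(np.int32), n=int(n), source=src)


def match_findings(predicted: FindingSet, truth: FindingSet) -> dict:
    """Overlap-based matching of predicted vs ground-truth findings.

    Each truth cluster overlapped by any predicted lesion pixel is one TP,
    otherwise one FN (so TP + FN = number of truth clusters). Each predicted
    component with no truth overlap is one FP; a predicted component touching
    one or more truth clusters contributes no FP however many it touches.
    """
    if predicted.label_image.shape != truth.label_image.shape:
        raise AlignmentError("finding sets are on different grids")
    pred_mask = predicted.label_image > 0
    tp = fn = 0
    truth.statuses = []
    for g in range(1, truth.n + 1):
        if pred_mask[truth.label_image == g].any():
            tp += 1
            truth.statuses.append("TP")
        else:
            fn += 1
            truth.statuses.append("FN")
    truth_mask = truth.label_image > 0
    fp = 0
    predicted.statuses = []
    for f in range(1, predicted.n + 1):
        if truth_mask[predicted.label_image == f].any():
            predicted.statuses.append("TP")
        else:
            predicted.statuses.append("FP")
            fp += 1
    return {"TP": tp, "FP": fp, "FN": fn, "n_truth": truth.n,
            "n_predicted": predicted.n}


# ------------------------------------------------------------------ FROC

@dataclass
class FROCCurve:
    thresholds: np.ndarray        # 1.00 -> 0.00, 101 values
    sensitivity: np.ndarray       # TP fraction of all truth findings
    fp_per_image: np.ndarray
    n_truth: int
    n_images: int

    def sensitivity_at(self, fp_rate: float) -> float:
        """Sensitivity at a given mean FP/image, linearly interpolated."""
        order = np.argsort(self.fp_per_image, kind="stable")
        x = self.fp_per_image[order]
        y = self.sensitivity[order]
        return float(np.interp(fp_rate, x, y))


def froc(prob_maps, risk_maps, min_area: int = 1) -> FROCCurve:
    """Free-response ROC over the 101-step threshold sweep 1.00 .. 0.00."""
    truth_sets = [extract_findings(rm, source="ground_truth")
                  for rm in risk_maps]
    n_truth = sum(t.n for t in truth_sets)
    if n_truth == 0:
        raise UndefinedMetricError("no ground-truth findings in the set")
    n_images = len(truth_sets)
    thresholds = np.round(np.linspace(1.0, 0.0, 101), 2)
    sens = np.empty(101)
    fpi = np.empty(101)
    for i, thr in enumerate(thresholds):
        tp = fp = 0
        for pm, ts in zip(prob_maps, truth_sets):
            pred = extract_findings(pm, threshold=thr, min_area=min_area)
            m = match_findings(pred, ts)
            tp += m["TP"]
            fp += m["FP"]
        sens[i] = tp / n_truth
        fpi[i] = fp / n_images
    return FROCCurve(thresholds=thresholds, sensitivity=sens,
                     fp_per_image=fpi, n_truth=n_truth, n_images=n_images)


def plot_froc(curves: dict, path):
    """Plot one or more FROC curves ({label: FROCCurve}) to PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        order = np.argsort(c.fp_per_image, kind="stable")
        ax.plot(c.fp_per_image[order], 100 * c.sensitivity[order],
                marker=".", ms=3, label=label)
    ax.set_xlabel("mean FP findings / image")
    ax.set_ylabel("sensitivity (%)")
    ax.legend()
    ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
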