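"""Evaluation metrics for growth prediction and segmentation quality.

Two complementary views: point-estimate metrics on the Monte-Carlo
means (balanced accuracy, precision, recall, growth-size MAE, Dice) and
distribution-fit metrics comparing the set of generated segmentations
with the set of annotator references (generalized energy distance with
d = 1 - IoU, and a balanced accuracy computed on the +/-2 standard
deviation growth interval).  Also provides the closest-annotator
selection rules and a stratified accuracy report by growth size and
time to predict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_io import GROWTH_THRESHOLD_MM, TIME_BIN_EDGES_DAYS
from .growth_inference import GrowthEstimate, classify_growth

__all__ = [
    "dice",
    "classification_metrics",
    "ged",
    "interval_confusion",
    "bacc_2std",
    "closest_annotator_growth",
    "closest_annotator_segmentation",
    "stratified_report",
    "mae_growth",
    "EvaluationReport",
    "evaluate_estimates",
]

#: marker for metrics whose denominator is empty
UNDEFINED = float("nan")

GROWTH_BIN_LABELS = ("<=0 mm", "(0,2] mm", "(2,5] mm", ">5 mm")
TIME_BIN_LABELS = ("<=6 mo", "(6,12] mo", "(12,24] mo", ">24 mo")


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A&B|/(|A|+|B|); both-empty masks score 1."""
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    if union == 0:
        return 1.0  # both empty: identical
    return float((a & b).sum() / union)


def classification_metrics(predicted, true) -> tuple[float, float, float]:
    """(balanced accuracy, precision, recall) for binary labels.

    Metrics with an empty denominator (no positives, no negatives, or
    no positive predictions) are returned as NaN.
    """
    yp = np.asarray(predicted, dtype=int)
    yt = np.asarray(true, dtype=int)
    if yp.shape != yt.shape:
        raise ValueError("label vectors differ in length")
    tp = int(((yp == 1) & (yt == 1)).sum())
    fp = int(((yp == 1) & (yt == 0)).sum())
    tn = int(((yp == 0) & (yt == 0)).sum())
    fn = int(((yp == 0) & (yt == 1)).sum())
    tpr = tp / (tp + fn) if tp + fn else UNDEFINED
    tnr = tn / (tn + fp) if tn + fp else UNDEFINED
    bacc = (tpr + tnr) / 2.0
    precision = tp / (tp + fp) if tp + fp else UNDEFINED
    return bacc, precision, tpr


def ged(pred_samples, gt_references) -> tuple[float, float, float, float]:
    """Generalized energy distance between mask sets with d = 1 - IoU.

    Returns (GED, two_cross, within_pred, within_gt) where
    GED^2 = two_cross - within_pred - within_gt, two_cross is twice the
    mean cross distance and the within terms are the mean pairwise
    distances inside each set (including self-pairs, which are 0).
    """
    if len(pred_samples) == 0 or len(gt_references) == 0:
        raise ValueError("both mask sets must be non-empty")
    preds = [np.asarray(m) > 0 for m in pred_samples]
    gts = [np.asarray(m) > 0 for m in gt_references]
    n, m = len(preds), len(gts)
    cross = sum(1.0 - _iou(a, b) for a in preds for b in gts) / (n * m)
    within_p = sum(1.0 - _iou(a, b) for a in preds for b in preds) / (n * n)
    within_g = sum(1.0 - _iou(a, b) for a in gts for b in gts) / (m * m)
    d2 = 2.0 * cross - within_p - within_g
    return float(np.sqrt(max(0.0, d2))), 2.0 * cross, within_p, within_g


def interval_confusion(estimate: GrowthEstimate, gt_growth_mm: float) -> str:
    """Confusion cell of the +/-2 std growth interval against 2 mm.

    TP: truth > 2 and interval lower bound > 2; FN: truth > 2 but lower
    bound <= 2; TN: truth <= 2 and upper bound <= 2; FP: truth <= 2 but
    upper bound > 2.
    """
    thr = GROWTH_THRESHOLD_MM
    lo, hi = estimate.interval_2std
    if gt_growth_mm > thr:
        return "TP" if lo > thr else "FN"
    return "TN" if hi <= thr else "FP"


def bacc_2std(estimates: list[GrowthEstimate], gt_growth_mm) -> float:
    """Balanced accuracy of the +/-2 std growth interval against 2 mm."""
    gt = np.asarray(gt_growth_mm, dtype=float)
    if len(estimates) != len(gt):
        raise ValueError("estimates and ground truths differ in length")
    cells = [interval_confusion(est, g) for est, g in zip(estimates, gt)]
    tp = cells.count("TP")
    fn = cells.count("FN")
    tn = cells.count("TN")
    fp = cells.count("FP")
    tpr = tp / (tp + fn) if tp + fn else UNDEFINED
    tnr = tn / (tn + fp) if tn + fp else UNDEFINED
    return (tpr + tnr) / 2.0


def closest_annotator_growth(estimate: GrowthEstimate, annotator_growth_mm) -> int:
    """Annotator whose growth reading is nearest the predicted growth
    distribution (1-D Mahalanobis distance |g - mean| / std; absolute
    difference when std is 0).  Ties go to the lowest index."""
    g = np.asarray(annotator_growth_mm, dtype=float)
    if g.size == 0:
        raise ValueError("no annotators given")
    if estimate.delta_std > 0:
        dist = np.abs(g - estimate.delta_mean) / estimate.delta_std
    else:
        dist = np.abs(g - estimate.delta_mean)
    return int(np.argmin(dist))


def closest_annotator_segmentation(pred_samples, annotator_masks) -> int:
    """Annotator whose reference mask has the highest mean Dice against
    the generated samples.  Ties go to the lowest index."""
    if len(pred_samples) == 0 or len(annotator_masks) == 0:
        raise ValueError("need at least one sample and one annotator mask")
    scores = [
        np.mean([dice(s, gt) for s in pred_samples]) for gt in annotator_masks
    ]
    return int(np.argmax(scores))


def _growth_bin(g_mm: float) -> int:
    if g_mm <= 0:
        return 0
    if g_mm <= 2:
        return 1
    if g_mm <= 5:
        return 2
    return 3


def _time_bin(elapsed_days: int) -> int:
    return int(np.searchsorted(TIME_BIN_EDGES_DAYS, elapsed_days))


def stratified_report(estimates, records) -> dict:
    """Accuracy of the growth call per (growth bin x time bin) cell.

    Returns {"accuracy": 4x4 array (growth x time, NaN where empty),
    "fraction": case fraction per cell, "accuracy_within_24mo":
    aggregate accuracy over the first three time bins}.
    """
    if len(estimates) != len(records):
        raise ValueError("estimates and records differ in length")
    correct = np.zeros((4, 4))
    count = np.zeros((4, 4))
    for est, rec in zip(estimates, records):
        gi = _growth_bin(rec.growth_mm)
        ti = _time_bin(rec.elapsed_days)
        pred = classify_growth(est)
        truth = int(rec.growth_mm > GROWTH_THRESHOLD_MM)
        count[gi, ti] += 1
        correct[gi, ti] += pred == truth
    with np.errstate(invalid="ignore"):
        acc = np.where(count > 0, correct / np.maximum(count, 1), UNDEFINED)
    within = count[:, :3].sum()
    acc24 = correct[:, :3].sum() / within if within else UNDEFINED
    return {
        "accuracy": acc,
        "fraction": count / max(count.sum(), 1),
        "counts": count.astype(int),
        "accuracy_within_24mo": acc24,
        "growth_bins": GROWTH_BIN_LABELS,
        "time_bins": TIME_BIN_LABELS,
    }


def mae_growth(estimates, gt_growth_mm) -> float:
    """Mean absolute error (mm) between predicted mean growth and truth."""
    gt = np.asarray(gt_growth_mm, dtype=float)
    if len(estimates) == 0:
        raise ValueError("no estimates")
    means = np.array([e.delta_mean for e in estimates])
    return float(np.abs(means - gt).mean())


@dataclass
class EvaluationReport:
    bacc: float
    precision: float
    recall: float
    mae_mm: float
    dice: float
    ged_pooled: float
    ged_per_case: float
    ged_components: tuple[float, float, float]  # (2x cross, within pred, within gt)
    bacc_2std: float
    stratified: dict
    n_records: int

    def to_dict(self) -> dict:
        return {
            "bacc": self.bacc,
            "precision": self.precision,
            "recall": self.recall,
            "mae_mm": self.mae_mm,
            "dice": self.dice,
            "ged_pooled": self.ged_pooled,
            "ged_per_case": self.ged_per_case,
            "ged_two_cross": self.ged_components[0],
            "ged_within_pred": self.ged_components[1],
            "ged_within_gt": self.ged_components[2],
            "bacc_2std": self.bacc_2std,
            "accuracy_within_24mo": self.stratified["accuracy_within_24mo"],
            "n_records": self.n_records,
        }


def evaluate_estimates(
    estimates,
    records,
    pred_mask_sets=None,
    n_ged_samples: int = 20,
) -> EvaluationReport:
    """Bundle all metrics for matched (estimate, record) lists.

    ``pred_mask_sets`` optionally provides, per record, a list of
    thresholded sample masks used for Dice (against the reference mask)
    and GED; when omitted the thresholded mean image is used for Dice
    and GED terms are reported as NaN.  The pooled GED treats all
    (sample, reference) pairs across the test set as one population;
    the per-case aggregation averages each case's components first.
    """
    if len(estimates) != len(records):
        raise ValueError("estimates and records differ in length")
    gt_growth = [r.growth_mm for r in records]
    y_true = [int(g > GROWTH_THRESHOLD_MM) for g in gt_growth]
    y_pred = [classify_growth(e) for e in estimates]
    bacc, prec, rec = classification_metrics(y_pred, y_true)
    mae = mae_growth(estimates, gt_growth)

    dices = []
    for est, r in zip(estimates, records):
        if r.mask_t1 is not None:
            dices.append(dice(est.mean_image > 0.5, r.mask_t1))
    mean_dice = float(np.mean(dices)) if dices else UNDEFINED

    if pred_mask_sets is not None:
        per_case = [
            ged(samples[:n_ged_samples], [r.mask_t1])
            for samples, r in zip(pred_mask_sets, records)
            if r.mask_t1 is not None
        ]
        comp = np.array([c[1:] for c in per_case])  # (n, 3)
        mean_comp = comp.mean(axis=0)
        d2 = mean_comp[0] - mean_comp[1] - mean_comp[2]
        ged_pooled = float(np.sqrt(max(0.0, d2)))
        ged_case = float(np.mean([c[0] for c in per_case]))
        components = tuple(float(x) for x in mean_comp)
    else:
        ged_pooled = ged_case = UNDEFINED
        components = (UNDEFINED, UNDEFINED, UNDEFINED)

    return EvaluationReport(
        bacc=bacc,
        precision=prec,
        recall=rec,
        mae_mm=mae,
        dice=mean_dice,
        ged_pooled=ged_pooled,
        ged_per_case=ged_case,
        ged_components=components,
        bacc_2std=bacc_2std(estimates, gt_growth),
        stratified=stratified_report(estimates, records),
        n_records=len(records),
    )
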