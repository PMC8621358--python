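"""Detection and segmentation evaluation.

Implements the standard object-detection protocol for a single 'spike'
class: greedy one-to-one matching of predictions to ground truth at an
IoU threshold, precision / recall / accuracy / F1 from the match counts,
interpolated average precision in both the VOC flavor (11 recall levels
0, 0.1, ..., 1) and the COCO flavor (101 recall points per threshold,
averaged over the IoU grid 0.50:0.05:0.95), plus pixel-level mask
metrics (Dice, Jaccard, class-averaged Dice and IoU) and reporting
stratified by spike visibility category.

Conventions worth noting:

* Matching is greedy in descending confidence; each prediction takes the
  unmatched ground truth of highest IoU if that IoU reaches the
  threshold, otherwise it is a false positive. Confidence ties break by
  higher IoU, then input order.
* A detection-level true negative is defined at the image level (a
  spike-free image with no predictions), since per-box true negatives do
  not exist.
* Undefined ratios (e.g. precision with no predictions) are reported as
  NaN with a warning — never silently as 0 — so degenerate reports are
  visibly degenerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import BinaryMask, BoxAnnotation

__all__ = [
    "MatchResult",
    "PRCurve",
    "EvalReport",
    "CategoryReport",
    "box_iou",
    "match_detections",
    "detection_scores",
    "pr_curve",
    "interpolated_ap",
    "ap_11point",
    "ap_coco",
    "COCO_IOU_THRESHOLDS",
    "mean_ap",
    "mask_metrics",
    "evaluate_by_category",
    "confusion_counts",
]

COCO_IOU_THRESHOLDS: tuple[float, ...] = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))


def box_iou(a: BoxAnnotation, b: BoxAnnotation) -> float:
    """Intersection over union of two boxes on half-open pixel areas."""
    if a.area <= 0 or b.area <= 0:
        raise ValueError("boxes must have positive area")
    iw = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    ih = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


@dataclass
class MatchResult:
    """Outcome of matching one image's (or pooled) predictions to ground truth."""

    matches: list[tuple[int, int, float]]   # (prediction index, gt index, IoU)
    tp: int
    fp: int
    fn: int
    tn: int = 0                              # image-level correct rejections
    iou_threshold: float = 0.5
    # per-prediction record in descending-confidence order:
    # (prediction index, confidence, matched gt index or None)
    prediction_outcomes: list[tuple[int, float, Optional[int]]] = field(default_factory=list)


def _sorted_prediction_order(preds: Sequence[BoxAnnotation], gts: Sequence[BoxAnnotation]) -> list[int]:
    """Indices in descending confidence; ties by best-IoU desc, then input order."""
    best_iou = [max((box_iou(p, g) for g in gts), default=0.0) for p in preds]
    return sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, -best_iou[i], i))


def match_detections(preds: Sequence[BoxAnnotation], gts: Sequence[BoxAnnotation],
                     iou_threshold: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground-truth boxes."""
    for p in preds:
        if p.confidence is None:
            raise ValueError("every prediction must carry a confidence score")
    matched_gt: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    outcomes: list[tuple[int, float, Optional[int]]] = []
    for i in _sorted_prediction_order(preds, gts):
        pred = preds[i]
        best_j, best = None, 0.0
        for j, gt in enumerate(gts):
            if j in matched_gt:
                continue
            iou = box_iou(pred, gt)
            if iou > best:
                best, best_j = iou, j
        if best_j is not None and best >= iou_threshold:
            matched_gt.add(best_j)
            matches.append((i, best_j, best))
            outcomes.append((i, pred.confidence, best_j))
        else:
            outcomes.append((i, pred.confidence, None))
    tp = len(matches)
    tn = int(len(gts) == 0 and len(preds) == 0)
    return MatchResult(
        matches=matches, tp=tp, fp=len(preds) - tp, fn=len(gts) - tp,
        tn=tn, iou_threshold=iou_threshold, prediction_outcomes=outcomes,
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def detection_scores(m: MatchResult) -> tuple[float, float, float, float]:
    """Precision, recall, accuracy and F1 from match counts.

    P = TP/(TP+FP), R = TP/(TP+FN), A = (TP+TN)/(TP+TN+FP+FN) with the
    image-level TN convention, F1 = 2PR/(P+R). Undefined ratios are NaN.
    """
    p = _safe_ratio(m.tp, m.tp + m.fp, "precision")
    r = _safe_ratio(m.tp, m.tp + m.fn, "recall")
    a = _safe_ratio(m.tp + m.tn, m.tp + m.tn + m.fp + m.fn, "accuracy")
    if np.isnan(p) or np.isnan(r) or (p + r) == 0:
        if not (np.isnan(p) or np.isnan(r)):
            warnings.warn("F1 undefined (P + R = 0); reporting NaN", stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2.0 * p * r / (p + r)
    return p, r, a, f1


@dataclass
class PRCurve:
    """Cumulative precision/recall along descending-confidence predictions."""

    precision: np.ndarray
    recall: np.ndarray
    interpolation: str = "none"


def _pooled_outcomes(preds_per_image: Sequence[Sequence[BoxAnnotation]],
                     gts_per_image: Sequence[Sequence[BoxAnnotation]],
                     iou_threshold: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Pool per-image greedy matches into (confidences, is_tp) sorted by confidence."""
    confs, is_tp = [], []
    n_gt = 0
    for preds, gts in zip(preds_per_image, gts_per_image):
        n_gt += len(gts)
        m = match_detections(preds, gts, iou_threshold)
        for _, conf, gt_idx in m.prediction_outcomes:
            confs.append(conf)
            is_tp.append(gt_idx is not None)
    confs = np.asarray(confs, dtype=float)
    is_tp = np.asarray(is_tp, dtype=bool)
    order = np.argsort(-confs, kind="stable")
    return confs[order], is_tp[order], n_gt


def pr_curve(preds_per_image: Sequence[Sequence[BoxAnnotation]],
             gts_per_image: Sequence[Sequence[BoxAnnotation]],
             iou_threshold: float = 0.5) -> PRCurve:
    """Dataset-level PR curve: matching is per image, ranking is global."""
    confs, is_tp, n_gt = _pooled_outcomes(preds_per_image, gts_per_image, iou_threshold)
    if n_gt == 0:
        raise ValueError("PR curve undefined without ground-truth boxes")
    tp_cum = np.cumsum(is_tp)
    k = np.arange(1, len(confs) + 1)
    return PRCurve(precision=tp_cum / k, recall=tp_cum / n_gt)


def interpolated_ap(curve: PRCurve, recall_points: np.ndarray) -> float:
    """Mean of max-precision-at-recall>=r over the given recall grid."""
    ap = 0.0
    for r in recall_points:
        mask = curve.recall >= r - 1e-12
        ap += float(curve.precision[mask].max()) if mask.any() else 0.0
    return ap / len(recall_points)


def ap_11point(preds_per_image: Sequence[Sequence[BoxAnnotation]],
               gts_per_image: Sequence[Sequence[BoxAnnotation]],
               iou_threshold: float = 0.5) -> float:
    """VOC-style AP: interpolated precision averaged over recalls 0, 0.1, ..., 1."""
    curve = pr_curve(preds_per_image, gts_per_image, iou_threshold)
    return interpolated_ap(curve, np.linspace(0.0, 1.0, 11))


def ap_coco(preds_per_image: Sequence[Sequence[BoxAnnotation]],
            gts_per_image: Sequence[Sequence[BoxAnnotation]]) -> tuple[dict[float, float], float]:
    """COCO-style AP: 101 recall points per IoU threshold in 0.50:0.05:0.95.

    Returns (AP per threshold, mean over the 10 thresholds).
    """
    recall_grid = np.linspace(0.0, 1.0, 101)
    per_threshold: dict[float, float] = {}
    for thr in COCO_IOU_THRESHOLDS:
        curve = pr_curve(preds_per_image, gts_per_image, thr)
        per_threshold[thr] = interpolated_ap(curve, recall_grid)
    return per_threshold, float(np.mean(list(per_threshold.values())))


def mean_ap(ap_per_class: Sequence[float]) -> float:
    """Arithmetic mean of per-class APs."""
    if len(ap_per_class) == 0:
        raise ValueError("mean AP of an empty list is undefined")
    return float(np.mean(ap_per_class))


def mask_metrics(pred: BinaryMask, gt: BinaryMask) -> dict[str, float]:
    """Pixel-level overlap scores between a predicted and ground-truth mask.

    Returns dice and jaccard on the spike class, their class-wise averages
    over spike and background (aDC, mean IoU), and pixel accuracy. An
    empty-vs-empty class scores 1.0.
    """
    if pred.labels.shape != gt.labels.shape:
        raise ValueError("prediction and ground truth must have the same shape")
    p = pred.labels.astype(bool)
    g = gt.labels.astype(bool)

    def _dice_jacc(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        inter = int((a & b).sum())
        sa, sb = int(a.sum()), int(b.sum())
        if sa + sb == 0:
            return 1.0, 1.0
        dice = 2.0 * inter / (sa + sb)
        union = sa + sb - inter
        return dice, inter / union

    dice_s, jacc_s = _dice_jacc(p, g)
    dice_b, jacc_b = _dice_jacc(~p, ~g)
    return {
        "dice": dice_s,
        "jaccard": jacc_s,
        "aDC": 0.5 * (dice_s + dice_b),
        "mean_iou": 0.5 * (jacc_s + jacc_b),
        "pixel_accuracy": float((p == g).mean()),
    }


@dataclass
class CategoryReport:
    category: str
    n_gt: int
    tp: int
    fn: int
    fp: int
    precision: float
    recall: float
    ap_11point: Optional[float]
    mean_tp_confidence: Optional[float]


@dataclass
class EvalReport:
    """Aggregate detection report with per-category breakdown."""

    precision: float
    recall: float
    accuracy: float
    f1: float
    ap: float
    iou_threshold: float
    per_category: dict[str, CategoryReport]

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(c) for c in self.per_category.values()]
        return pd.DataFrame(rows)


def _nearest_gt_category(pred: BoxAnnotation, gts: Sequence[BoxAnnotation]) -> str:
    if not gts:
        return "uncategorized"
    px, py = pred.center
    dists = [(gx - px) ** 2 + (gy - py) ** 2 for gx, gy in (g.center for g in gts)]
    return gts[int(np.argmin(dists))].category or "uncategorized"


def evaluate_by_category(preds_per_image: Sequence[Sequence[BoxAnnotation]],
                         gts_per_image: Sequence[Sequence[BoxAnnotation]],
                         iou_threshold: float = 0.5) -> EvalReport:
    """Global evaluation plus per-visibility-category attribution.

    Matching runs once per image at ``iou_threshold``; each TP/FN is
    attributed to its ground-truth box's category, each FP to the
    category of the nearest ground truth by box-center distance (or
    'uncategorized' on images without ground truth). The per-category AP
    restricts ground truth to that category while keeping every
    prediction attributed to it. ``mean_tp_confidence`` is the mean
    confidence of matched true positives.
    """
    for gts in gts_per_image:
        for g in gts:
            if g.category is None:
                raise ValueError("every ground-truth box needs a category tag")

    total_tp = total_fp = total_fn = total_tn = 0
    cat_tp: dict[str, int] = {}
    cat_fn: dict[str, int] = {}
    cat_fp: dict[str, int] = {}
    cat_gt: dict[str, int] = {}
    cat_conf: dict[str, list[float]] = {}
    cat_preds: dict[str, list[list[BoxAnnotation]]] = {}
    cat_gts: dict[str, list[list[BoxAnnotation]]] = {}
    categories = sorted({g.category for gts in gts_per_image for g in gts})

    for preds, gts in zip(preds_per_image, gts_per_image):
        m = match_detections(preds, gts, iou_threshold)
        total_tp += m.tp
        total_fp += m.fp
        total_fn += m.fn
        total_tn += m.tn
        for g in gts:
            cat_gt[g.category] = cat_gt.get(g.category, 0) + 1
        matched_gts = {j for _, j, _ in m.matches}
        per_image_cat_preds: dict[str, list[BoxAnnotation]] = {}
        for i, conf, gt_idx in m.prediction_outcomes:
            cat = gts[gt_idx].category if gt_idx is not None else _nearest_gt_category(preds[i], gts)
            per_image_cat_preds.setdefault(cat, []).append(preds[i])
            if gt_idx is not None:
                cat_tp[cat] = cat_tp.get(cat, 0) + 1
                cat_conf.setdefault(cat, []).append(conf)
            else:
                cat_fp[cat] = cat_fp.get(cat, 0) + 1
        for j, g in enumerate(gts):
            if j not in matched_gts:
                cat_fn[g.category] = cat_fn.get(g.category, 0) + 1
        for cat in categories:
            cat_preds.setdefault(cat, []).append(per_image_cat_preds.get(cat, []))
            cat_gts.setdefault(cat, []).append([g for g in gts if g.category == cat])

    p, r, a, f1 = detection_scores(MatchResult([], total_tp, total_fp, total_fn, tn=total_tn,
                                               iou_threshold=iou_threshold))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap = (ap_11point(preds_per_image, gts_per_image, iou_threshold)
              if any(gts for gts in gts_per_image) else float("nan"))

    per_category: dict[str, CategoryReport] = {}
    for cat in categories:
        tp = cat_tp.get(cat, 0)
        fn = cat_fn.get(cat, 0)
        fp = cat_fp.get(cat, 0)
        n_gt = cat_gt.get(cat, 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cp, cr, _, _ = detection_scores(MatchResult([], tp, fp, fn, iou_threshold=iou_threshold))
            cat_ap = ap_11point(cat_preds[cat], cat_gts[cat], iou_threshold) if n_gt else None
        confs = cat_conf.get(cat)
        per_category[cat] = CategoryReport(
            category=cat, n_gt=n_gt, tp=tp, fn=fn, fp=fp,
            precision=cp, recall=cr, ap_11point=cat_ap,
            mean_tp_confidence=(float(np.mean(confs)) if confs else None),
        )
    return EvalReport(precision=p, recall=r, accuracy=a, f1=f1, ap=ap,
                      iou_threshold=iou_threshold, per_category=per_category)


def confusion_counts(m: MatchResult) -> pd.DataFrame:
    """2x2 detection confusion table (TN uses the image-level convention)."""
    return pd.DataFrame(
        [[m.tp, m.fn], [m.fp, m.tn]],
        index=pd.Index(["actual_spike", "actual_background"]),
        columns=["predicted_spike", "predicted_background"],
    )
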