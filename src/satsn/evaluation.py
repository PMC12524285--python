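"""Detection/classification metrics and ethogram statistics.

Implements precision / recall / F1, per-class average precision as the area
under the all-point interpolated precision-recall curve, mAP as the plain
mean of per-class APs, confusion matrices, and time-budget / event-count
summaries of per-frame behavior labels.

Keyframe protocol: predictions are matched to ground-truth boxes class-wise
in confidence-descending order at IoU >= ``iou_threshold`` (default 0.5);
each ground-truth box can be matched once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .datamodel import BEHAVIORS, AvaRecord
from .tracker import iou

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")


def precision_recall_f1(counts: MatchCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = harmonic mean (fractions in [0,1]).

    Zero-denominator cases return 0 (a warning is logged); this keeps metric
    aggregation total-function and is the documented convention.
    """
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    if counts.tp + counts.fp == 0 or counts.tp + counts.fn == 0:
        logger.warning("zero denominator in precision/recall; reporting 0 by convention")
    f1 = f1_from_pr(p, r)
    return p, r, f1


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    s = precision + recall
    return 2.0 * precision * recall / s if s > 0 else 0.0


@dataclass
class RankedPrediction:
    """One scored prediction for AP computation."""

    key: object            # grouping key of the frame/keyframe (e.g. (video, second))
    box: np.ndarray        # pixel or normalized box, consistent with GT
    score: float
    class_id: int


def average_precision(
    predictions: list[RankedPrediction],
    ground_truth: list[tuple[object, np.ndarray]],
    iou_threshold: float = 0.5,
) -> float:
    """AP for one class: area under the all-point interpolated PR curve.

    ``ground_truth`` holds (key, box) pairs of the class; each GT box may be
    matched by at most one prediction, greedily in confidence-descending
    order at IoU >= threshold. Returns NaN if the class has no ground truth.
    """
    n_gt = len(ground_truth)
    if n_gt == 0:
        logger.warning("no ground truth for class; AP undefined")
        return float("nan")
    gt_by_key: dict[object, list[np.ndarray]] = {}
    for key, box in ground_truth:
        gt_by_key.setdefault(key, []).append(np.asarray(box, dtype=float))
    matched: dict[object, list[bool]] = {k: [False] * len(v) for k, v in gt_by_key.items()}

    order = sorted(range(len(predictions)),
                   key=lambda i: (-predictions[i].score, i))
    tps = np.zeros(len(order))
    for rank, i in enumerate(order):
        p = predictions[i]
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gt_by_key.get(p.key, [])):
            if matched[p.key][j]:
                continue
            v = iou(np.asarray(p.box, dtype=float), g)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[p.key][best_j] = True
            tps[rank] = 1.0

    if len(order) == 0:
        return 0.0
    cum_tp = np.cumsum(tps)
    precision = cum_tp / np.arange(1, len(order) + 1)
    recall = cum_tp / n_gt
    # all-point interpolation: precision envelope, integrate over recall steps
    p_env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for p_val, r_val, is_tp in zip(p_env, recall, tps):
        if is_tp:
            ap += (r_val - prev_r) * p_val
            prev_r = r_val
    return float(ap)


def mean_ap(ap_values) -> float:
    """Arithmetic mean of per-class APs; NaN entries are excluded with a warning."""
    vals = np.asarray(list(ap_values), dtype=float)
    if vals.size == 0:
        raise ValueError("mean_ap requires at least one AP value")
    mask = np.isfinite(vals)
    if not mask.all():
        logger.warning("excluding %d undefined AP value(s) from mAP", (~mask).sum())
    if not mask.any():
        raise ValueError("all AP values are undefined")
    return float(vals[mask].mean())


def confusion_matrix(pred_labels, true_labels, k: int) -> np.ndarray:
    """k×k counts; entry (i, j) counts samples with true class i predicted j."""
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.size and (pred.min() < 0 or pred.max() >= k or true.min() < 0 or true.max() >= k):
        raise ValueError(f"labels out of range [0, {k})")
    return _sk_confusion(true, pred, labels=np.arange(k))


@dataclass
class EvalResult:
    """Per-class metrics plus mAP and a confusion matrix."""

    per_class_ap: dict[str, float]
    per_class_prf: dict[str, tuple[float, float, float]]
    map_value: float
    confusion: np.ndarray
    iou_threshold: float
    n_classes: int = 4

    def to_dict(self) -> dict:
        return {
            "mAP": self.map_value,
            "iou_threshold": self.iou_threshold,
            "per_class_ap": self.per_class_ap,
            "per_class_precision_recall_f1": {
                k: list(v) for k, v in self.per_class_prf.items()
            },
            "confusion_matrix": self.confusion.tolist(),
        }


def evaluate_ava(predictions: list[AvaRecord], pred_scores: list[float],
                 ground_truth: list[AvaRecord], iou_threshold: float = 0.5
                 ) -> EvalResult:
    """Keyframe evaluation of predicted AVA rows against ground truth.

    Per class: AP over score-ranked predictions and operating-point P/R/F1
    (all predictions as emitted). The confusion matrix pairs each GT box with
    the highest-scoring prediction on the same keyframe at IoU >= threshold.
    """
    if len(predictions) != len(pred_scores):
        raise ValueError("one score per predicted record required")
    per_class_ap: dict[str, float] = {}
    per_class_prf: dict[str, tuple[float, float, float]] = {}
    for cid, name in enumerate(BEHAVIORS, start=1):
        preds = [
            RankedPrediction(key=(r.video_id, r.timestamp_s),
                             box=np.asarray(r.box_norm), score=s, class_id=cid)
            for r, s in zip(predictions, pred_scores) if r.action_id == cid
        ]
        gts = [((r.video_id, r.timestamp_s), np.asarray(r.box_norm))
               for r in ground_truth if r.action_id == cid]
        per_class_ap[name] = average_precision(preds, gts, iou_threshold)
        tp = _count_tp(preds, gts, iou_threshold)
        counts = MatchCounts(tp=tp, fp=len(preds) - tp, fn=len(gts) - tp)
        per_class_prf[name] = precision_recall_f1(counts)

    # confusion matrix over matched (gt, best prediction) pairs
    true_ids, pred_ids = [], []
    pred_by_key: dict[object, list[tuple[AvaRecord, float]]] = {}
    for r, s in zip(predictions, pred_scores):
        pred_by_key.setdefault((r.video_id, r.timestamp_s), []).append((r, s))
    for g in ground_truth:
        cands = pred_by_key.get((g.video_id, g.timestamp_s), [])
        best, best_s = None, -1.0
        for r, s in cands:
            if iou(np.asarray(r.box_norm), np.asarray(g.box_norm)) >= iou_threshold \
                    and s > best_s:
                best, best_s = r, s
        if best is not None:
            true_ids.append(g.action_id - 1)
            pred_ids.append(best.action_id - 1)
    conf = confusion_matrix(pred_ids, true_ids, len(BEHAVIORS)) if true_ids else \
        np.zeros((len(BEHAVIORS), len(BEHAVIORS)), dtype=int)

    return EvalResult(per_class_ap=per_class_ap, per_class_prf=per_class_prf,
                      map_value=mean_ap(per_class_ap.values()), confusion=conf,
                      iou_threshold=iou_threshold)


def _count_tp(preds: list[RankedPrediction],
              gts: list[tuple[object, np.ndarray]], thr: float) -> int:
    gt_by_key: dict[object, list[np.ndarray]] = {}
    for key, box in gts:
        gt_by_key.setdefault(key, []).append(box)
    matched = {k: [False] * len(v) for k, v in gt_by_key.items()}
    tp = 0
    for p in sorted(preds, key=lambda p: -p.score):
        best, bj = 0.0, -1
        for j, g in enumerate(gt_by_key.get(p.key, [])):
            if not matched[p.key][j]:
                v = iou(np.asarray(p.box), g)
                if v > best:
                    best, bj = v, j
        if bj >= 0 and best >= thr:
            matched[p.key][bj] = True
            tp += 1
    return tp


# ---------------------------------------------------------------------------
# Ethogram statistics
# ---------------------------------------------------------------------------

def label_runs(labels) -> list[tuple[int, int, int]]:
    """Maximal constant runs of a label sequence as (label, start, length)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def time_budget(track_labels, fps: float, min_event_s: float = 1.0
                ) -> dict[str, dict[str, float]]:
    """Per-behavior duration (s) and event counts for one label sequence.

    An event is a maximal run of one label whose duration is at least
    ``min_event_s`` seconds. Durations over all behaviors sum to the sequence
    length divided by fps (conservation).
    """
    out = {b: {"duration_s": 0.0, "events": 0} for b in BEHAVIORS}
    min_len = min_event_s * fps
    for action_id, _start, length in label_runs(track_labels):
        name = BEHAVIORS[action_id - 1]
        out[name]["duration_s"] += length / fps
        if length >= min_len:
            out[name]["events"] += 1
    return out


def windowed_time_budget(track_labels, fps: float, window_s: float,
                         min_event_s: float = 1.0) -> list[dict[str, dict[str, float]]]:
    """Time budget per consecutive window of ``window_s`` seconds."""
    labels = np.asarray(track_labels)
    step = int(round(window_s * fps))
    if step < 1:
        raise ValueError("window shorter than one frame")
    return [time_budget(labels[i : i + step], fps, min_event_s)
            for i in range(0, labels.size, step)]
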