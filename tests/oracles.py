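"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own code paths: the Kalman oracle is a
plain textbook filter over explicit matrices, and the AP oracle enumerates
the precision-recall curve point by point.
"""

from __future__ import annotations

import numpy as np


class ReferenceKalman:
    """Textbook linear Kalman filter (predict / update over dense matrices)."""

    def __init__(self, x0: np.ndarray, P0: np.ndarray, F: np.ndarray,
                 H: np.ndarray, Q: np.ndarray, R: np.ndarray):
        self.x = np.asarray(x0, dtype=float).copy()
        self.P = np.asarray(P0, dtype=float).copy()
        self.F, self.H, self.Q, self.R = (np.asarray(m, dtype=float)
                                          for m in (F, H, Q, R))

    def predict(self) -> None:
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q

    def update(self, z: np.ndarray) -> None:
        z = np.asarray(z, dtype=float)
        S = self.H @ self.P @ self.H.T + self.R
        K = np.linalg.solve(S.T, (self.P @ self.H.T).T).T
        self.x = self.x + K @ (z - self.H @ self.x)
        I = np.eye(self.P.shape[0])
        self.P = (I - K @ self.H) @ self.P


def brute_force_ap(outcomes: list[bool], n_gt: int) -> float:
    """AP from a ranked TP/FP outcome sequence by explicit PR enumeration.

    Walks the ranking, records (recall, precision) at every true positive,
    applies the precision envelope (max precision at recall >= r), and sums
    the recall increments times the enveloped precision.
    """
    if n_gt == 0:
        raise ValueError("need ground truth")
    points = []
    tp = 0
    for rank, is_tp in enumerate(outcomes, start=1):
        if is_tp:
            tp += 1
            points.append((tp / n_gt, tp / rank))
    ap = 0.0
    prev_recall = 0.0
    for i, (recall, _prec) in enumerate(points):
        envelope = max(p for _r, p in points[i:])
        ap += (recall - prev_recall) * envelope
        prev_recall = recall
    return ap


def outcome_geometry(outcomes: list[bool], n_gt: int):
    """Build boxes realizing a TP/FP ranking for the package's AP matcher.

    GT boxes are disjoint unit squares; the k-th true positive sits exactly
    on the k-th GT box, false positives live in empty space. Scores strictly
    decrease in rank order.
    """
    gt_boxes = [np.array([10.0 * i, 0.0, 10.0 * i + 1.0, 1.0]) for i in range(n_gt)]
    preds = []
    tp_seen = 0
    for rank, is_tp in enumerate(outcomes):
        if is_tp:
            box = gt_boxes[tp_seen].copy()
            tp_seen += 1
        else:
            box = np.array([1000.0 + 10.0 * rank, 0.0, 1001.0 + 10.0 * rank, 1.0])
        preds.append((box, 1.0 - rank * 0.01))
    return gt_boxes, preds


def all_outcome_sequences(max_preds: int, n_gt: int):
    """Every TP/FP ranking with at most n_gt true positives."""
    for n_pred in range(max_preds + 1):
        for bits in range(2 ** n_pred):
            seq = [(bits >> k) & 1 == 1 for k in range(n_pred)]
            if sum(seq) <= n_gt:
                yield seq
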