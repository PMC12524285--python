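"""Glue between the synthetic data, the ROI router, the network, and the metrics.

This is where clips become routed training/evaluation samples and where the
detect -> track -> route -> classify inference chain is assembled.
"""

from __future__ import annotations

import numpy as np

from .datamodel import (
    BEHAVIORS,
    AvaRecord,
    BoundingBox,
    Detection,
    Keypoint,
    PipelineConfig,
)
from .evaluation import average_precision, RankedPrediction
from .net import SatsnArchConfig, SatsnModel
from .roi import route_inputs
from .synthetic import GroundTruth
from .tracker import TrackerConfig, TrackRecord, track_video
from . import io as sio


def routed_sample(
    clip_frames: np.ndarray,
    gt: GroundTruth,
    pipe: PipelineConfig,
    arch: SatsnArchConfig,
    scheme: str,
    training: bool,
    agent: int = 0,
    clip_id: str = "",
) -> tuple[np.ndarray, np.ndarray, int]:
    """One (slow, fast, zero-based label) triple from a clip's ground truth.

    Box and keypoint are taken at the clip's central frame; in training mode
    the ground-truth label steers the licking-only mouth substitution.
    """
    mid = gt.n_frames // 2
    box = BoundingBox.from_array(gt.boxes[agent, mid])
    mouth = Keypoint(float(gt.mouths[agent, mid, 0]), float(gt.mouths[agent, mid, 1]))
    label = gt.clip_label(agent)
    tsi = route_inputs(
        clip_frames, box, mouth,
        label_hint=label if training else None,
        scheme=scheme, config=pipe,
        slow_res=arch.slow_res, fast_res=arch.fast_res, clip_id=clip_id,
    )
    return tsi.slow_frames, tsi.fast_frames, label - 1


def build_routed_dataset(clipset, pipe: PipelineConfig, arch: SatsnArchConfig,
                         scheme: str, training: bool
                         ) -> list[tuple[np.ndarray, np.ndarray, int]]:
    return [
        routed_sample(clip.frames, gt, pipe, arch, scheme, training,
                      clip_id=clip.clip_id)
        for clip, gt, _scene in clipset
    ]


def classification_ap(model: SatsnModel, samples, boxes, clip_ids
                      ) -> dict[str, float]:
    """Per-class AP over score-ranked clip-level predictions.

    Each held-out clip contributes one box; for class c every clip is scored
    with the model's probability for c and matched against the clips whose
    true label is c (standard ranking AP at the keyframe level).
    """
    slows = np.stack([s for s, _f, _y in samples])
    fasts = np.stack([f for _s, f, _y in samples])
    labels = np.array([y for _s, _f, y in samples])
    probs = np.vstack([
        model.predict_proba(slows[i : i + 8], fasts[i : i + 8])
        for i in range(0, len(samples), 8)
    ])
    out: dict[str, float] = {}
    for c, name in enumerate(BEHAVIORS):
        preds = [RankedPrediction(key=cid, box=np.asarray(b), score=float(probs[i, c]),
                                  class_id=c + 1)
                 for i, (cid, b) in enumerate(zip(clip_ids, boxes))]
        gts = [(cid, np.asarray(b)) for (cid, b), y in zip(zip(clip_ids, boxes), labels)
               if y == c]
        out[name] = average_precision(preds, gts, iou_threshold=0.5)
    return out


def infer_ava(
    clip_frames: np.ndarray,
    detections: list[Detection],
    model: SatsnModel,
    pipe: PipelineConfig,
    fps: float,
    video_id: str,
    tracker_config: TrackerConfig | None = None,
) -> tuple[list[AvaRecord], list[float]]:
    """Full inference chain: track, route per tracked box at 1 Hz keyframes,
    classify, and emit predicted AVA rows with confidences."""
    records = track_video(detections, tracker_config)
    by_frame: dict[int, list[TrackRecord]] = {}
    for r in records:
        by_frame.setdefault(r.frame, []).append(r)
    det_by_frame = sio.group_by_frame(detections)
    H, W = clip_frames.shape[1:3]
    arch = model.config
    rows: list[AvaRecord] = []
    scores: list[float] = []
    n_frames = clip_frames.shape[0]
    window = pipe.required_clip_length()
    n_seconds = int(np.floor((n_frames - 1) / fps)) + 1
    for s in range(n_seconds):
        t = int(round(s * fps))
        for rec in by_frame.get(t, []):
            x1, y1, x2, y2 = rec.box
            try:
                box = BoundingBox(x1, y1, x2, y2)
            except ValueError:
                continue
            mouth = _nearest_mouth(det_by_frame.get(t, []), box)
            # sample the two-stream window centered on the keyframe so the
            # box and the frames describe the same moment
            lo = int(np.clip(t - window // 2, 0, max(n_frames - window, 0)))
            frames_win = clip_frames[lo : lo + window]
            tsi = route_inputs(frames_win, box, mouth, label_hint=None,
                               scheme=pipe.routing_scheme, config=pipe,
                               slow_res=arch.slow_res, fast_res=arch.fast_res,
                               clip_id=video_id)
            probs = model.predict_proba(tsi.slow_frames[None], tsi.fast_frames[None])[0]
            c = int(np.argmax(probs))
            norm = (max(x1 / W, 0.0), max(y1 / H, 0.0),
                    min(x2 / W, 1.0), min(y2 / H, 1.0))
            if not (norm[0] < norm[2] and norm[1] < norm[3]):
                continue
            rows.append(AvaRecord(video_id, s, norm, c + 1, rec.track_id))
            scores.append(float(probs[c]))
    return rows, scores


def _nearest_mouth(dets: list[Detection], box: BoundingBox) -> Keypoint | None:
    cx, cy = box.center
    best, best_d = None, np.inf
    for d in dets:
        dx, dy = d.box.center
        dist = (dx - cx) ** 2 + (dy - cy) ** 2
        if dist < best_d:
            best, best_d = d.mouth, dist
    return best
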