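"""Observation-centric multi-object tracking (OC-SORT style).

Each track runs a constant-velocity Kalman filter over the state
[cx, cy, s, r, vcx, vcy, vs] (box center, area, aspect ratio and their
velocities; the aspect ratio is modeled as constant). Three
observation-centric mechanisms improve robustness through occlusions:

* ORU — on re-activation after a gap, the filter is rolled back to the
  posterior at the last real observation and re-run along a virtual
  trajectory linearly interpolated between the last and the new observation,
  which cancels the drift accumulated while coasting;
* OCM — the association cost adds a momentum term: the angle between the
  observation-derived track direction and the track-to-candidate direction,
  normalized by pi, weighted by lambda;
* OCR — a recovery pass matching unmatched tracks' *last observations*
  (not predictions) to remaining detections by generalized IoU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datamodel import BoundingBox, Detection

# ---------------------------------------------------------------------------
# Box overlap
# ---------------------------------------------------------------------------

def _box_arr(b) -> np.ndarray:
    return b.as_array() if isinstance(b, BoundingBox) else np.asarray(b, dtype=float)


def iou(a, b) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    a, b = _box_arr(a), _box_arr(b)
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(ix2 - ix1, 0.0) * max(iy2 - iy1, 0.0)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def giou(a, b) -> float:
    """Generalized IoU in (-1, 1]: IoU minus enclosing-box slack."""
    a, b = _box_arr(a), _box_arr(b)
    v = iou(a, b)
    cx1, cy1 = min(a[0], b[0]), min(a[1], b[1])
    cx2, cy2 = max(a[2], b[2]), max(a[3], b[3])
    hull = (cx2 - cx1) * (cy2 - cy1)
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(ix2 - ix1, 0.0) * max(iy2 - iy1, 0.0)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    union = area_a + area_b - inter
    return v - (hull - union) / hull if hull > 0 else 0.0


# ---------------------------------------------------------------------------
# Kalman filter
# ---------------------------------------------------------------------------

def box_to_z(box) -> np.ndarray:
    """Box [x1,y1,x2,y2] -> measurement [cx, cy, s=area, r=aspect]."""
    b = _box_arr(box)
    w, h = b[2] - b[0], b[3] - b[1]
    return np.array([b[0] + w / 2.0, b[1] + h / 2.0, w * h, w / h])


def z_to_box(z: np.ndarray) -> np.ndarray:
    """Measurement [cx, cy, s, r] -> box [x1,y1,x2,y2]."""
    w = math.sqrt(max(z[2] * z[3], 1e-12))
    h = z[2] / w
    return np.array([z[0] - w / 2.0, z[1] - h / 2.0, z[0] + w / 2.0, z[1] + h / 2.0])


def _transition_matrix() -> np.ndarray:
    F = np.eye(7)
    F[0, 4] = F[1, 5] = F[2, 6] = 1.0
    return F


def _observation_matrix() -> np.ndarray:
    return np.eye(4, 7)


@dataclass
class KalmanState:
    """State vector, covariance, and the per-step system matrices."""

    x: np.ndarray                     # (7,)
    P: np.ndarray                     # (7,7)
    F: np.ndarray = field(default_factory=_transition_matrix)
    H: np.ndarray = field(default_factory=_observation_matrix)
    Q: np.ndarray = field(default_factory=lambda: _default_Q(1.0))
    R: np.ndarray = field(default_factory=lambda: _default_R(1.0))

    def copy(self) -> "KalmanState":
        return KalmanState(self.x.copy(), self.P.copy(), self.F, self.H, self.Q, self.R)

    @property
    def box(self) -> np.ndarray:
        return z_to_box(self.x[:4])


def _default_Q(scale: float) -> np.ndarray:
    Q = np.eye(7)
    Q[4:, 4:] *= 0.01
    Q[6, 6] *= 0.01
    return Q * scale


def _default_R(scale: float) -> np.ndarray:
    R = np.eye(4)
    R[2:, 2:] *= 10.0
    return R * scale


def init_state(box, q_scale: float = 1.0, r_scale: float = 1.0) -> KalmanState:
    x = np.zeros(7)
    x[:4] = box_to_z(box)
    P = np.eye(7) * 10.0
    P[4:, 4:] *= 100.0  # unobserved initial velocities
    return KalmanState(x=x, P=P, Q=_default_Q(q_scale), R=_default_R(r_scale))


def kf_predict(state: KalmanState) -> KalmanState:
    """x <- Fx, P <- FPF' + Q. Covariance trace never shrinks for Q >= 0."""
    if not np.all(np.isfinite(state.x)):
        raise ValueError(f"non-finite state {state.x}")
    x = state.x.copy()
    if x[2] + x[6] <= 0:  # area would go nonpositive: freeze area velocity
        x[6] = 0.0
    x = state.F @ x
    P = state.F @ state.P @ state.F.T + state.Q
    P = 0.5 * (P + P.T)
    return replace(state, x=x, P=P)


def kf_update(state: KalmanState, z) -> KalmanState:
    """Standard update: K = PH'(HPH'+R)^-1; x += K(z - Hx); P = (I-KH)P."""
    z = np.asarray(z, dtype=float)
    if z.shape == (4,) and z[2] <= 0:
        raise ValueError(f"nonpositive area in measurement {z}")
    H, R, P = state.H, state.R, state.P
    S = H @ P @ H.T + R
    try:
        K = P @ H.T @ np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular innovation covariance: {S}") from exc
    innov = z - H @ state.x
    if not np.all(np.isfinite(innov)):
        raise ValueError(f"non-finite innovation {innov}")
    x = state.x + K @ innov
    P_new = (np.eye(7) - K @ H) @ P
    P_new = 0.5 * (P_new + P_new.T)
    return replace(state, x=x, P=P_new)


# ---------------------------------------------------------------------------
# Virtual trajectory + re-update
# ---------------------------------------------------------------------------

def virtual_trajectory(z_t1, t1: int, z_t2, t2: int, t: int) -> np.ndarray:
    """Linear interpolation of each box parameter between two observations."""
    if not (t1 < t < t2):
        raise ValueError(f"need t1 < t < t2, got t1={t1}, t={t}, t2={t2}")
    a, b = _box_arr(z_t1), _box_arr(z_t2)
    frac = (t - t1) / (t2 - t1)
    return a + frac * (b - a)


@dataclass
class Track:
    """One tracked individual with observation history and rollback snapshot."""

    track_id: int
    state: KalmanState
    history: list[tuple[int, np.ndarray]]            # [(t, observed box)]
    snapshot: tuple[int, KalmanState] | None = None  # posterior at last real obs
    hit_streak: int = 0
    time_since_update: int = 0
    age: int = 0
    last_score: float = 1.0

    @property
    def last_obs(self) -> tuple[int, np.ndarray]:
        return self.history[-1]

    @property
    def status(self) -> str:
        if self.time_since_update > 0:
            return "lost"
        return "active" if self.hit_streak >= 1 else "tentative"


def oru_reupdate(track: Track, z_t2, t2: int) -> Track:
    """Roll back to the posterior at the last observation and re-run the
    filter along the virtual trajectory, finishing with the real update at t2."""
    if track.snapshot is None:
        raise ValueError("track has no stored posterior to roll back to")
    t1, post = track.snapshot
    if t2 <= t1:
        raise ValueError(f"re-detection time {t2} must exceed last observation time {t1}")
    state = post.copy()
    z1 = track.history[-1][1]
    for t in range(t1 + 1, t2):
        state = kf_predict(state)
        state = kf_update(state, box_to_z(virtual_trajectory(z1, t1, z_t2, t2, t)))
    state = kf_predict(state)
    state = kf_update(state, box_to_z(z_t2))
    track.state = state
    return track


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

@dataclass
class TrackerConfig:
    """Association and lifecycle parameters (repo defaults, all overridable)."""

    lambda_momentum: float = 0.2
    delta_t: int = 3
    iou_min: float = 0.3
    max_age: int = 30
    min_hits: int = 3
    ocr_giou_min: float = -0.2
    q_scale: float = 1.0
    r_scale: float = 1.0
    use_ocm: bool = True
    use_oru: bool = True
    use_ocr: bool = True

    def __post_init__(self) -> None:
        if self.lambda_momentum < 0 or self.delta_t < 1 or self.max_age < 1:
            raise ValueError("lambda >= 0, delta_t >= 1, max_age >= 1 required")


def _angle_cost(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        return 0.0
    cos = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return math.acos(cos) / math.pi


def ocm_cost(track: Track, det: Detection, lam: float, delta_t: int) -> float:
    """Association cost: (1 - IoU(predicted, det)) + lambda * direction term.

    The direction term compares the observation-derived motion of the track
    (center displacement over delta_t observed frames) with the direction
    from the last observation to the candidate; tracks with fewer than
    delta_t + 1 observations contribute zero momentum cost.
    """
    c_iou = 1.0 - iou(track.state.box, det.box)
    if lam == 0.0:
        return c_iou
    hist = track.history
    if len(hist) < delta_t + 1:
        return c_iou
    z_now = hist[-1][1]
    z_old = hist[-1 - delta_t][1]
    center = lambda b: np.array([(b[0] + b[2]) / 2.0, (b[1] + b[3]) / 2.0])
    u = center(z_now) - center(z_old)
    v = box_to_z(det.box)[:2] - center(z_now)
    return c_iou + lam * _angle_cost(u, v)


def associate(tracks: list[Track], detections: list[Detection], config: TrackerConfig
              ) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-cost bipartite matching with post-assignment IoU gating.

    Returns (matches as (track_index, det_index), unmatched track indices,
    unmatched detection indices). Ties are broken deterministically by
    (track index, detection index).
    """
    if not tracks or not detections:
        return [], list(range(len(tracks))), list(range(len(detections)))
    lam = config.lambda_momentum if config.use_ocm else 0.0
    cost = np.zeros((len(tracks), len(detections)))
    for i, tr in enumerate(tracks):
        for j, d in enumerate(detections):
            cost[i, j] = ocm_cost(tr, d, lam, config.delta_t)
    # deterministic tie-break: infinitesimal preference for low (i, j)
    tie = (np.arange(len(tracks))[:, None] * len(detections)
           + np.arange(len(detections))[None, :])
    rows, cols = linear_sum_assignment(cost + 1e-10 * tie)
    matches, um_t, um_d = [], set(range(len(tracks))), set(range(len(detections)))
    for i, j in zip(rows, cols):
        if iou(tracks[i].state.box, detections[j].box) >= config.iou_min:
            matches.append((i, j))
            um_t.discard(i)
            um_d.discard(j)
    return matches, sorted(um_t), sorted(um_d)


def ocr_pass(tracks: list[Track], detections: list[Detection],
             track_idx: list[int], det_idx: list[int], config: TrackerConfig
             ) -> list[tuple[int, int]]:
    """Recovery pass: greedily match last observations to detections by GIoU."""
    pairs = []
    for i in track_idx:
        for j in det_idx:
            g = giou(tracks[i].last_obs[1], detections[j].box)
            if g >= config.ocr_giou_min:
                pairs.append((-g, i, j))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    out = []
    for _, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        out.append((i, j))
        used_t.add(i)
        used_d.add(j)
    return out


# ---------------------------------------------------------------------------
# Video-level tracking
# ---------------------------------------------------------------------------

@dataclass
class TrackRecord:
    """One output row: a confirmed track box at one frame."""

    frame: int
    track_id: int
    box: np.ndarray
    score: float
    det_gt_id: int | None  # ground-truth identity of the matched detection, if any


def track_video(detections: list[Detection], config: TrackerConfig | None = None
                ) -> list[TrackRecord]:
    """Run the tracker over a detection stream; deterministic given inputs."""
    config = config or TrackerConfig()
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame_index, []).append(d)
    if not by_frame:
        return []
    n_frames = max(by_frame) + 1

    tracks: list[Track] = []
    next_id = 1
    records: list[TrackRecord] = []

    for t in range(n_frames):
        dets = by_frame.get(t, [])
        for tr in tracks:
            tr.state = kf_predict(tr.state)
            tr.age += 1
            tr.time_since_update += 1

        matches, um_t, um_d = associate(tracks, dets, config)
        if config.use_ocr and um_t and um_d:
            extra = ocr_pass(tracks, dets, um_t, um_d, config)
            matches.extend(extra)
            um_t = [i for i in um_t if i not in {i for i, _ in extra}]
            um_d = [j for j in um_d if j not in {j for _, j in extra}]

        matched_gt: dict[int, int | None] = {}
        for i, j in matches:
            tr, det = tracks[i], dets[j]
            gap = tr.time_since_update
            if gap > 1 and config.use_oru and tr.snapshot is not None:
                oru_reupdate(tr, det.box.as_array(), t)
            else:
                tr.state = kf_update(tr.state, box_to_z(det.box))
            tr.history.append((t, det.box.as_array()))
            tr.snapshot = (t, tr.state.copy())
            tr.hit_streak = tr.hit_streak + 1 if gap <= 1 else 1
            tr.time_since_update = 0
            tr.last_score = det.score
            matched_gt[tr.track_id] = det.gt_id

        for j in um_d:
            det = dets[j]
            st = init_state(det.box, config.q_scale, config.r_scale)
            tracks.append(Track(track_id=next_id, state=st,
                                history=[(t, det.box.as_array())],
                                snapshot=(t, st.copy()), hit_streak=1,
                                time_since_update=0, last_score=det.score))
            matched_gt[next_id] = det.gt_id
            next_id += 1

        for tr in tracks:
            if tr.time_since_update == 0 and (tr.hit_streak >= config.min_hits
                                              or t < config.min_hits):
                records.append(TrackRecord(frame=t, track_id=tr.track_id,
                                           box=tr.state.box.copy(),
                                           score=tr.last_score,
                                           det_gt_id=matched_gt.get(tr.track_id)))
        tracks = [tr for tr in tracks if tr.time_since_update <= config.max_age]

    return records


def count_id_switches(records: list[TrackRecord]) -> int:
    """ID switches against ground-truth identities carried on the detections."""
    per_gt: dict[int, list[tuple[int, int]]] = {}
    for r in records:
        if r.det_gt_id is None:
            continue
        per_gt.setdefault(r.det_gt_id, []).append((r.frame, r.track_id))
    switches = 0
    for seq in per_gt.values():
        seq.sort()
        for (_, a), (_, b) in zip(seq, seq[1:]):
            if a != b:
                switches += 1
    return switches


def records_to_mot_rows(records: list[TrackRecord]
                        ) -> list[tuple[int, int, float, float, float, float, float]]:
    rows = []
    for r in sorted(records, key=lambda r: (r.frame, r.track_id)):
        x1, y1, x2, y2 = r.box
        rows.append((r.frame, r.track_id, x1, y1, x2 - x1, y2 - y1, r.score))
    return rows
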