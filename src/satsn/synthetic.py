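"""Synthetic multi-agent scenes with motion-signature behaviors.

The generator emulates fixed-camera enclosure footage: a static textured
background with a vertical tree trunk and a feeding trough, plus one or more
long-necked agents rendered as textured ellipses with a neck and head
appendage. Behaviors are encoded through the cues the downstream network is
meant to exploit:

* ``walking``  — body translation >= 2 px/frame, head up;
* ``standing`` — static body (<= 0.2 px/frame), head up, mouth away from
  tree and trough;
* ``eating``   — static body, head lowered into the trough band, slow
  large-amplitude mouth oscillation;
* ``licking``  — static body, mouth in contact with the tree column, fast
  small-amplitude mouth oscillation with an intermittently visible tongue.

Licking and eating therefore differ only in head placement and the temporal
frequency of the mouth-region dynamics — the body is nearly static in both —
which gives the keypoint-guided mouth crop genuine discriminative signal.

Everything is driven by one ``numpy`` Generator: the same seed reproduces
frames, ground truth, and perturbed detections byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .datamodel import (
    BEHAVIOR_TO_ACTION_ID,
    BEHAVIORS,
    KP_VISIBLE,
    AvaRecord,
    BoundingBox,
    Detection,
    Keypoint,
    VideoClip,
)
from . import io as sio

logger = logging.getLogger(__name__)

# Agent geometry (pixels)
BODY_RX, BODY_RY = 17.0, 9.0
HEAD_R = 4.5
NECK_R = 3.0
MOUTH_R = 2.5

# Behavior-signature dynamics: (amplitude px, frequency cycles/frame)
LICK_AMP, LICK_FREQ = 2.5, 0.40
EAT_AMP, EAT_FREQ = 3.5, 0.07
WALK_SPEED_RANGE = (2.0, 3.5)  # px/frame, satisfies the >= 2 px/frame signature


@dataclass
class SceneConfig:
    """Layout and noise model of one synthetic scene."""

    height: int = 160
    width: int = 256
    n_agents: int = 1
    n_frames: int = 64
    fps: float = 30.0
    tree_x: float = 64.0          # column center of the tree trunk
    tree_halfwidth: float = 6.0
    trough: tuple[float, float, float, float] = (150.0, 132.0, 240.0, 152.0)  # x1,y1,x2,y2
    occluders: tuple[tuple[float, float], ...] = ()   # vertical strips (x_min, x_max)
    sigma_box: float = 1.5        # detection corner jitter (px)
    sigma_kp: float = 1.0         # keypoint jitter (px)
    miss_rate: float = 0.02      # random per-frame detection dropout
    sensor_noise: float = 2.0     # per-frame additive intensity noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_box < 0 or self.sigma_kp < 0 or not (0 <= self.miss_rate <= 1):
            raise ValueError("noise parameters must be nonnegative, miss_rate in [0,1]")
        if self.n_frames < 1 or self.n_agents < 1:
            raise ValueError("need at least one frame and one agent")


@dataclass
class AgentScript:
    """Behavior timeline plus starting pose for one agent.

    ``intervals`` is a list of (start_frame, end_frame, behavior) tiles that
    must cover [0, n_frames) without overlap. ``facing`` is +1 (rightward) or
    -1 and fixes which side the neck extends to.
    """

    agent_id: int
    intervals: list[tuple[int, int, str]]
    start: tuple[float, float]
    velocity: tuple[float, float] = (0.0, 0.0)
    facing: int = 1
    #: "near_tree" puts a standing agent in a licking-like pose with the
    #: mouth resting at the trunk but never oscillating — the confuser that
    #: makes the licking class depend on mouth-region dynamics.
    pose_variant: str = "default"

    def behavior_at(self, t: int) -> str:
        for s, e, b in self.intervals:
            if s <= t < e:
                return b
        raise ValueError(f"frame {t} not covered by script of agent {self.agent_id}")

    def validate(self, n_frames: int) -> None:
        ivs = sorted(self.intervals)
        if not ivs or ivs[0][0] != 0 or ivs[-1][1] != n_frames:
            raise ValueError("behavior intervals must tile [0, n_frames)")
        for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if e0 != s1:
                raise ValueError("behavior intervals must tile [0, n_frames) without gaps/overlap")
        for _, _, b in ivs:
            if b not in BEHAVIORS:
                raise ValueError(f"unknown behavior {b!r}")


@dataclass
class GroundTruth:
    """Per-frame, per-agent ground truth arrays (agent axis first)."""

    boxes: np.ndarray        # (A, T, 4) pixel x1,y1,x2,y2
    mouths: np.ndarray       # (A, T, 2) pixel x,y
    labels: np.ndarray       # (A, T) int action ids 1..4
    occluded: np.ndarray     # (A, T) bool
    agent_ids: np.ndarray    # (A,) int

    @property
    def n_agents(self) -> int:
        return int(self.boxes.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.boxes.shape[1])

    def clip_label(self, agent_index: int) -> int:
        """Majority action id of one agent over the clip."""
        vals, counts = np.unique(self.labels[agent_index], return_counts=True)
        return int(vals[np.argmax(counts)])


# ---------------------------------------------------------------------------
# Pose model
# ---------------------------------------------------------------------------

def _agent_pose(script: AgentScript, scene: SceneConfig, t: int) -> dict:
    """Deterministic kinematics: body center, head center, mouth point at frame t."""
    behavior = script.behavior_at(t)
    f = float(script.facing)
    cx, cy = script.start
    if behavior == "walking":
        # integrate velocity over walking frames so far, reflecting at borders
        vx, vy = script.velocity
        x, y = cx, cy
        margin_x, margin_y = BODY_RX + 10, BODY_RY + 38
        for _ in range(t):
            x += vx
            y += vy
            if not (margin_x <= x <= scene.width - margin_x):
                vx = -vx
                x = float(np.clip(x, margin_x, scene.width - margin_x))
            if not (margin_y <= y <= scene.height - BODY_RY - 4):
                vy = -vy
                y = float(np.clip(y, margin_y, scene.height - BODY_RY - 4))
        cx, cy = x, y
        f = 1.0 if vx >= 0 else -1.0

    if behavior == "standing" and script.pose_variant == "near_tree":
        # investigative pose: head extended toward the trunk, no contact
        head = (cx + f * 28.0, cy - 10.0)
        mouth = (head[0] + f * (HEAD_R + 1.0), head[1])
        osc = 0.0
    elif behavior in ("walking", "standing"):
        head = (cx + f * 14.0, cy - 32.0)
        mouth = (head[0] + f * (HEAD_R + 1.0), head[1])
        osc = 0.0
    elif behavior == "licking":
        head = (cx + f * 28.0, cy - 10.0)
        osc = LICK_AMP * math.sin(2.0 * math.pi * LICK_FREQ * t)
        mouth = (head[0] + f * (HEAD_R + 1.0 + max(osc, 0.0)), head[1])
    else:  # eating
        tx1, ty1, tx2, ty2 = scene.trough
        head_y = 0.5 * (ty1 + ty2)
        osc = EAT_AMP * math.sin(2.0 * math.pi * EAT_FREQ * t)
        head = (cx + f * 18.0 + f * max(osc, 0.0), head_y + 0.3 * osc)
        mouth = (head[0] + f * (HEAD_R + 1.0), head[1])
    return {"behavior": behavior, "body": (cx, cy), "head": head, "mouth": mouth,
            "facing": f, "osc": osc}


def _pose_box(pose: dict, scene: SceneConfig) -> BoundingBox:
    cx, cy = pose["body"]
    hx, hy = pose["head"]
    mx, my = pose["mouth"]
    x1 = min(cx - BODY_RX, hx - HEAD_R - 1, mx - MOUTH_R) - 1
    x2 = max(cx + BODY_RX, hx + HEAD_R + 1, mx + MOUTH_R) + 1
    y1 = min(cy - BODY_RY, hy - HEAD_R - 1, my - MOUTH_R) - 1
    y2 = max(cy + BODY_RY, hy + HEAD_R + 1, my + MOUTH_R) + 1
    x1c, y1c = max(x1, 0.0), max(y1, 0.0)
    x2c, y2c = min(x2, float(scene.width)), min(y2, float(scene.height))
    if (x1c, y1c, x2c, y2c) != (x1, y1, x2, y2):
        logger.warning("agent box clamped to frame: (%.1f,%.1f,%.1f,%.1f)", x1, y1, x2, y2)
    return BoundingBox(x1c, y1c, max(x2c, x1c + 2.0), max(y2c, y1c + 2.0))


# ---------------------------------------------------------------------------
# Rendering primitives (windowed array composition; no graphics stack)
# ---------------------------------------------------------------------------

def _paint_disc(img: np.ndarray, cx: float, cy: float, r: float, color: np.ndarray) -> None:
    H, W = img.shape[:2]
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, W)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, H)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    img[y0:y1, x0:x1][mask] = color


def _paint_ellipse_textured(img: np.ndarray, cx: float, cy: float, rx: float, ry: float,
                            color: np.ndarray) -> None:
    H, W = img.shape[:2]
    x0, x1 = max(int(cx - rx) - 1, 0), min(int(cx + rx) + 2, W)
    y0, y1 = max(int(cy - ry) - 1, 0), min(int(cy + ry) + 2, H)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    # body-local patchwork texture translates rigidly with the agent
    tex = 28.0 * np.sin(0.9 * (xx - cx)) * np.sin(0.7 * (yy - cy))
    patch = np.clip(color[None, None, :] + tex[:, :, None], 0, 255)
    img[y0:y1, x0:x1][mask] = patch[mask]


def _paint_segment(img: np.ndarray, p0: tuple[float, float], p1: tuple[float, float],
                   r: float, color: np.ndarray) -> None:
    n = max(int(math.hypot(p1[0] - p0[0], p1[1] - p0[1]) / (r * 0.75)), 1)
    for i in range(n + 1):
        a = i / n
        _paint_disc(img, p0[0] + a * (p1[0] - p0[0]), p0[1] + a * (p1[1] - p0[1]), r, color)


def _background(scene: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    H, W = scene.height, scene.width
    bg = np.empty((H, W, 3), dtype=float)
    bg[:] = (92.0, 118.0, 72.0)
    bg += rng.normal(0.0, 6.0, size=(H, W, 1))
    # tree trunk
    x0 = int(scene.tree_x - scene.tree_halfwidth)
    x1 = int(scene.tree_x + scene.tree_halfwidth)
    bark = np.array([96.0, 72.0, 44.0])
    stripes = 10.0 * np.sin(np.arange(H) * 0.6)[:, None, None]
    bg[:, x0:x1] = bark[None, None, :] + stripes
    # trough
    tx1, ty1, tx2, ty2 = (int(v) for v in scene.trough)
    bg[ty1:ty2, tx1:tx2] = (122.0, 122.0, 128.0)
    bg[ty1 : ty1 + 2, tx1:tx2] = (80.0, 80.0, 86.0)
    return bg


def _render_agent(img: np.ndarray, pose: dict) -> None:
    body_color = np.array([198.0, 168.0, 108.0])
    head_color = np.array([176.0, 142.0, 88.0])
    mouth_color = np.array([58.0, 40.0, 30.0])
    tongue_color = np.array([214.0, 120.0, 124.0])
    cx, cy = pose["body"]
    hx, hy = pose["head"]
    mx, my = pose["mouth"]
    _paint_segment(img, (cx + pose["facing"] * 6.0, cy - 4.0), (hx, hy), NECK_R,
                   head_color)
    _paint_ellipse_textured(img, cx, cy, BODY_RX, BODY_RY, body_color)
    _paint_disc(img, hx, hy, HEAD_R, head_color)
    _paint_disc(img, mx, my, MOUTH_R, mouth_color)
    if pose["behavior"] in ("licking", "eating") and pose["osc"] > 0.0:
        # tongue flick / chewing bolus: bright patch past the mouth, blinking
        # at the behavior's oscillation frequency (50% duty cycle)
        _paint_disc(img, mx + pose["facing"] * 2.2, my, 2.4, tongue_color)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def render_scene(scene: SceneConfig, scripts: Sequence[AgentScript]) -> tuple[VideoClip, GroundTruth]:
    """Render a scene and its exact ground truth; deterministic given the seed."""
    for s in scripts:
        s.validate(scene.n_frames)
    rng = np.random.default_rng(scene.seed)
    bg = _background(scene, rng)
    A, T = len(scripts), scene.n_frames
    frames = np.empty((T, scene.height, scene.width, 3), dtype=np.uint8)
    boxes = np.zeros((A, T, 4))
    mouths = np.zeros((A, T, 2))
    labels = np.zeros((A, T), dtype=int)
    occluded = np.zeros((A, T), dtype=bool)

    # pre-draw sensor noise so agent count does not alter the noise stream
    noise = rng.normal(0.0, scene.sensor_noise, size=(T, scene.height, scene.width, 1)) \
        if scene.sensor_noise > 0 else None

    for t in range(T):
        img = bg.copy()
        for a, script in enumerate(scripts):
            pose = _agent_pose(script, scene, t)
            _render_agent(img, pose)
            box = _pose_box(pose, scene)
            boxes[a, t] = box.as_array()
            mouths[a, t] = pose["mouth"]
            labels[a, t] = BEHAVIOR_TO_ACTION_ID[pose["behavior"]]
            ccx = 0.5 * (box.x1 + box.x2)
            occluded[a, t] = any(lo <= ccx <= hi for lo, hi in scene.occluders)
        for lo, hi in scene.occluders:
            img[:, int(lo) : int(hi)] = (40.0, 48.0, 40.0)
        if noise is not None:
            img = img + noise[t]
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)

    gt = GroundTruth(boxes=boxes, mouths=mouths, labels=labels, occluded=occluded,
                     agent_ids=np.array([s.agent_id for s in scripts]))
    clip = VideoClip(clip_id=f"scene{scene.seed}", frames=frames, fps=scene.fps)
    return clip, gt


def perturb_detections(
    gt: GroundTruth,
    sigma: float,
    sigma_kp: float,
    miss_rate: float,
    occluders: Sequence[tuple[float, float]],
    seed: int,
) -> list[Detection]:
    """Emulate an upstream pose detector: jittered boxes/keypoints with dropouts.

    A detection is dropped when the agent center lies inside an occluder strip
    or, independently, with probability ``miss_rate``. Box corners receive
    zero-mean Gaussian noise ``sigma``, the mouth keypoint ``sigma_kp``, and
    the confidence is uniform on [0.5, 1].
    """
    if sigma < 0 or sigma_kp < 0 or not (0 <= miss_rate <= 1):
        raise ValueError("sigma, sigma_kp >= 0 and miss_rate in [0,1] required")
    rng = np.random.default_rng(seed)
    dets: list[Detection] = []
    for t in range(gt.n_frames):
        for a in range(gt.n_agents):
            b = gt.boxes[a, t]
            cx = 0.5 * (b[0] + b[2])
            drop = any(lo <= cx <= hi for lo, hi in occluders)
            # draw rng values unconditionally so the stream is stable
            u_miss = rng.uniform()
            jb = rng.normal(0.0, sigma, size=4) if sigma > 0 else np.zeros(4)
            jk = rng.normal(0.0, sigma_kp, size=2) if sigma_kp > 0 else np.zeros(2)
            score = float(rng.uniform(0.5, 1.0))
            if drop or u_miss < miss_rate:
                continue
            x1, y1, x2, y2 = b + jb
            if x2 <= x1:
                x1, x2 = x2 - 0.5, x1 + 0.5
            if y2 <= y1:
                y1, y2 = y2 - 0.5, y1 + 0.5
            mx, my = gt.mouths[a, t] + jk
            dets.append(
                Detection(
                    frame_index=t,
                    box=BoundingBox(x1, y1, x2, y2),
                    score=score,
                    mouth=Keypoint(float(mx), float(my), KP_VISIBLE),
                    gt_id=int(gt.agent_ids[a]),
                )
            )
    return dets


# ---------------------------------------------------------------------------
# Scripts and datasets
# ---------------------------------------------------------------------------

def single_behavior_script(
    behavior: str, scene: SceneConfig, rng: np.random.Generator, agent_id: int = 0
) -> AgentScript:
    """A whole-clip script performing one behavior at a plausible location."""
    facing = 1 if rng.uniform() < 0.5 else -1
    vel = (0.0, 0.0)
    H, W = scene.height, scene.width
    if behavior == "licking":
        # body offset so the mouth rests on the tree surface
        cx = scene.tree_x - facing * (scene.tree_halfwidth + 28.0 + HEAD_R + 1.0)
        cy = float(rng.uniform(H * 0.35, H * 0.65))
    elif behavior == "eating":
        tx1, _, tx2, _ = scene.trough
        cx = float(rng.uniform(tx1 + 10, tx2 - 10)) - facing * 18.0
        cx = float(np.clip(cx, 40.0, W - 44.0))
        cy = scene.trough[1] - 28.0 + float(rng.uniform(-4, 4))
    elif behavior == "walking":
        speed = float(rng.uniform(*WALK_SPEED_RANGE))
        vel = (facing * speed, float(rng.uniform(-0.3, 0.3)))
        cx = float(rng.uniform(W * 0.3, W * 0.7))
        cy = float(rng.uniform(H * 0.45, H * 0.7))
    elif behavior == "standing":
        if rng.uniform() < 0.5:
            # near-tree confuser: the mouth rests 2-5 px short of the trunk
            # and never oscillates or shows a tongue. The gap is at or below
            # the pixel scale of the downscaled full-body view, so gross
            # position and coarse geometry cannot separate this pose from
            # licking; a native-resolution mouth crop sees both the gap and
            # — the robust cue — the absence of the blinking tongue.
            gap = float(rng.uniform(2.0, 5.0))
            offset = scene.tree_halfwidth + 28.0 + HEAD_R + 1.0 + gap
            if scene.tree_x - offset < BODY_RX + 2:
                facing = -1  # left side too tight: approach from the right
            cx = scene.tree_x - facing * offset
            cy = float(rng.uniform(H * 0.35, H * 0.65))
            return AgentScript(agent_id=agent_id,
                               intervals=[(0, scene.n_frames, behavior)],
                               start=(cx, cy), facing=facing, pose_variant="near_tree")
        # away from tree and trough so the label is unambiguous
        cx = float(rng.uniform(scene.tree_x + 60, W - 40))
        cy = float(rng.uniform(H * 0.35, H * 0.6))
    else:
        raise ValueError(f"unknown behavior {behavior!r}")
    return AgentScript(agent_id=agent_id, intervals=[(0, scene.n_frames, behavior)],
                       start=(cx, cy), velocity=vel, facing=facing)


def rule_based_classify(gt: GroundTruth, scene: SceneConfig, agent_index: int = 0) -> int:
    """Threshold classifier on clean ground truth; documents task solvability.

    Walking if mean centroid displacement > 1 px/frame; else licking if the
    mouth sits at the tree surface *and* oscillates (a near-tree standing
    pose has a static mouth); else eating if the mouth sits in the trough
    band; else standing.
    """
    boxes = gt.boxes[agent_index]
    cents = 0.5 * (boxes[:, :2] + boxes[:, 2:])
    disp = np.linalg.norm(np.diff(cents, axis=0), axis=1).mean() if len(cents) > 1 else 0.0
    if disp > 1.0:
        return BEHAVIOR_TO_ACTION_ID["walking"]
    mouth = gt.mouths[agent_index]
    tree_dist = np.abs(mouth[:, 0] - scene.tree_x) - scene.tree_halfwidth
    mouth_motion = float(mouth[:, 0].std() + mouth[:, 1].std())
    if np.median(tree_dist) < 6.0 and mouth_motion > 0.5:
        return BEHAVIOR_TO_ACTION_ID["licking"]
    tx1, ty1, tx2, ty2 = scene.trough
    in_trough = (mouth[:, 0] >= tx1 - 6) & (mouth[:, 0] <= tx2 + 6) \
        & (mouth[:, 1] >= ty1 - 6) & (mouth[:, 1] <= ty2 + 6)
    if np.median(in_trough.astype(float)) > 0.5:
        return BEHAVIOR_TO_ACTION_ID["eating"]
    return BEHAVIOR_TO_ACTION_ID["standing"]


def gt_to_ava_records(gt: GroundTruth, scene: SceneConfig, clip_id: str) -> list[AvaRecord]:
    """Ground truth at 1 Hz keyframes as normalized AVA rows."""
    recs: list[AvaRecord] = []
    H, W = float(scene.height), float(scene.width)
    n_seconds = int(math.floor((gt.n_frames - 1) / scene.fps)) + 1
    for s in range(n_seconds):
        t = int(round(s * scene.fps))
        if t >= gt.n_frames:
            break
        for a in range(gt.n_agents):
            x1, y1, x2, y2 = gt.boxes[a, t]
            box = (max(x1 / W, 0.0), max(y1 / H, 0.0), min(x2 / W, 1.0), min(y2 / H, 1.0))
            recs.append(AvaRecord(clip_id, s, box, int(gt.labels[a, t]), int(gt.agent_ids[a])))
    return recs


def make_clip_set(
    n_clips: int,
    seed: int,
    scene_template: SceneConfig | None = None,
    behaviors: Sequence[str] = BEHAVIORS,
) -> list[tuple[VideoClip, GroundTruth, SceneConfig]]:
    """Class-balanced in-memory clip set (one single-behavior agent per clip)."""
    template = scene_template or SceneConfig()
    out = []
    for i in range(n_clips):
        behavior = behaviors[i % len(behaviors)]
        clip_seed = (seed * 100003 + i * 7919) % (2**31 - 1)
        scene = dataclasses.replace(template, seed=clip_seed, n_agents=1)
        rng = np.random.default_rng(clip_seed + 1)
        script = single_behavior_script(behavior, scene, rng, agent_id=0)
        clip, gt = render_scene(scene, [script])
        clip.clip_id = f"clip_{i:04d}_{behavior}"
        out.append((clip, gt, scene))
    return out


def make_fixture_dataset(
    out_dir: str | os.PathLike,
    n_clips: int = 40,
    seed: int = 0,
    scene_template: SceneConfig | None = None,
    force: bool = False,
    write_frames: bool = True,
) -> dict:
    """Write a class-balanced fixture dataset: frames, AVA CSVs, detections.

    Layout: ``clips/<clip_id>/frame_%06d.png``, ``detections/<clip_id>.jsonl``,
    ``train.csv`` / ``test.csv`` (8:2 split), and ``manifest.json`` recording
    the seed so the dataset can be reproduced identically.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    (out / "clips").mkdir(parents=True, exist_ok=True)
    (out / "detections").mkdir(parents=True, exist_ok=True)

    clipset = make_clip_set(n_clips, seed, scene_template)
    all_records: dict[str, list[AvaRecord]] = {}
    for clip, gt, scene in clipset:
        if write_frames:
            sio.write_frame_dir(clip, out / "clips" / clip.clip_id)
        dets = perturb_detections(gt, scene.sigma_box, scene.sigma_kp, scene.miss_rate,
                                  scene.occluders, seed=scene.seed + 2)
        sio.write_detection_stream(dets, out / "detections" / f"{clip.clip_id}.jsonl")
        all_records[clip.clip_id] = gt_to_ava_records(gt, scene, clip.clip_id)

    ids = sorted(all_records)
    train_ids, test_ids = sio.split_dataset(ids, [8, 2], seed=seed)
    train_rows = [r for cid in sorted(train_ids) for r in all_records[cid]]
    test_rows = [r for cid in sorted(test_ids) for r in all_records[cid]]
    sio.write_ava_csv(train_rows, out / "train.csv")
    sio.write_ava_csv(test_rows, out / "test.csv")

    manifest = {
        "seed": seed,
        "n_clips": n_clips,
        "scene": dataclasses.asdict(scene_template or SceneConfig()),
        "train_clips": sorted(train_ids),
        "test_clips": sorted(test_ids),
        "wrote_frames": write_frames,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
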