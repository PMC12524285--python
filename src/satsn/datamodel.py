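"""Domain types shared across the pipeline.

The atomic observation is a :class:`Detection`: one animal in one frame,
described by a body bounding box, a detector confidence, and a single mouth
keypoint. Behavior annotations travel as :class:`AvaRecord` rows (normalized
keyframe boxes with an action label and an entity id), and a
:class:`PipelineConfig` carries the sampling / routing / training knobs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Behavior classes in canonical order; action ids are 1-based into this tuple.
BEHAVIORS: tuple[str, ...] = ("licking", "standing", "walking", "eating")

#: action_id (1..4) -> behavior name
ACTION_ID_TO_BEHAVIOR: dict[int, str] = {i + 1: b for i, b in enumerate(BEHAVIORS)}
BEHAVIOR_TO_ACTION_ID: dict[str, int] = {b: i + 1 for i, b in enumerate(BEHAVIORS)}

# Keypoint visibility flags (COCO convention)
KP_ABSENT = 0
KP_OCCLUDED = 1
KP_VISIBLE = 2


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, origin top-left, x right, y down."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        for v in (self.x1, self.y1, self.x2, self.y2):
            if not math.isfinite(v):
                raise ValueError(f"non-finite box coordinate: {self}")
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(f"degenerate box (need x1<x2, y1<y2): {self}")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=float)

    @staticmethod
    def from_array(a: Sequence[float]) -> "BoundingBox":
        x1, y1, x2, y2 = (float(v) for v in a)
        return BoundingBox(x1, y1, x2, y2)


@dataclass(frozen=True)
class Keypoint:
    """One 2D keypoint with a visibility flag.

    ``visible`` follows the COCO convention: 0 = absent (coordinates are
    meaningless and must be ignored), 1 = present but occluded, 2 = visible.
    """

    x: float
    y: float
    visible: int = KP_VISIBLE

    def __post_init__(self) -> None:
        if self.visible not in (KP_ABSENT, KP_OCCLUDED, KP_VISIBLE):
            raise ValueError(f"visibility flag must be 0/1/2, got {self.visible}")


@dataclass(frozen=True)
class Detection:
    """One detected animal in one frame: body box + confidence + mouth keypoint."""

    frame_index: int
    box: BoundingBox
    score: float
    mouth: Keypoint
    gt_id: int | None = None  # optional ground-truth identity (synthetic streams)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0,1], got {self.score}")


@dataclass(frozen=True)
class AvaRecord:
    """One behavior annotation row: normalized keyframe box + action + entity."""

    video_id: str
    timestamp_s: int
    box_norm: tuple[float, float, float, float]
    action_id: int
    entity_id: int

    def __post_init__(self) -> None:
        x1, y1, x2, y2 = self.box_norm
        if not (0.0 <= x1 < x2 <= 1.0 and 0.0 <= y1 < y2 <= 1.0):
            raise ValueError(f"normalized box out of range or degenerate: {self.box_norm}")
        if self.action_id not in ACTION_ID_TO_BEHAVIOR:
            raise ValueError(f"unknown action_id {self.action_id}")

    @property
    def behavior(self) -> str:
        return ACTION_ID_TO_BEHAVIOR[self.action_id]


@dataclass
class VideoClip:
    """A clip held in memory as a stack of H×W×3 uint8 frames."""

    clip_id: str
    frames: np.ndarray  # (T_raw, H, W, 3) uint8
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[0] < 1 or self.frames.shape[3] != 3:
            raise ValueError(f"frames must be (T,H,W,3) with T>=1, got {self.frames.shape}")
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))


@dataclass
class TrainingConfig:
    batch_size: int = 4
    epochs: int = 200
    learning_rate: float = 0.02
    momentum: float = 0.9
    augment: bool = True


@dataclass
class PipelineConfig:
    """Sampling, routing, and training knobs for the two-stream pipeline.

    ``T`` slow frames are sampled with temporal stride ``tau``; the fast
    pathway samples ``alpha * T`` frames over the same window and runs with a
    ``beta``-scaled channel budget. ``crop_size`` is the side of the
    keypoint-centered mouth patch in source pixels.
    """

    T: int = 4
    tau: int = 4
    alpha: int = 4
    beta: float = 0.125
    crop_size: int = 128
    routing_scheme: str = "B"
    num_classes: int = 4
    seed: int = 0
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        if self.routing_scheme not in ("A", "B", "C"):
            raise ValueError(f"routing_scheme must be A, B or C, got {self.routing_scheme!r}")
        if not (self.alpha > 1 or self.alpha == 1):
            raise ValueError("alpha must be >= 1")
        if not (0.0 < self.beta < 1.0):
            raise ValueError(f"beta must be in (0,1), got {self.beta}")
        if self.crop_size <= 0:
            raise ValueError("crop_size must be positive")
        if self.T < 1 or self.tau < 1:
            raise ValueError("T and tau must be >= 1")

    def required_clip_length(self) -> int:
        return self.T * self.tau

    def with_scheme(self, scheme: str) -> "PipelineConfig":
        return replace(self, routing_scheme=scheme)
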