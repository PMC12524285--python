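"""Keypoint-centered mouth cropping and spatial-adaptive slow/fast input routing.

Three routing schemes control what each pathway sees:

* ``A`` — both pathways receive the full-body box (baseline);
* ``B`` — fast pathway receives the mouth crop, slow pathway the full body;
* ``C`` — slow pathway receives the mouth crop, fast pathway the full body.

During training the mouth substitution is applied only to samples labeled as
licking (other behaviors keep full-body inputs in both pathways). At
inference no label exists, so the scheme is applied whenever the mouth
keypoint is visible, with a full-body fallback otherwise; the decision taken
is recorded on the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .datamodel import (
    KP_ABSENT,
    BEHAVIOR_TO_ACTION_ID,
    BoundingBox,
    Keypoint,
    PipelineConfig,
)

FULL_BODY = "full_body"
MOUTH_CROP = "mouth_crop"


@dataclass
class TwoStreamInput:
    """Routed slow/fast frame stacks for one clip sample."""

    slow_frames: np.ndarray  # (T, s, s, 3) float32, centered in [-0.5, 0.5]
    fast_frames: np.ndarray  # (alpha*T, s_f, s_f, 3) float32, centered in [-0.5, 0.5]
    scheme: str
    clip_id: str
    slow_content: str
    fast_content: str

    def __post_init__(self) -> None:
        if self.scheme not in ("A", "B", "C"):
            raise ValueError(f"scheme must be A/B/C, got {self.scheme!r}")


def crop_region(frame: np.ndarray, center: tuple[float, float] | Keypoint,
                size: int) -> np.ndarray:
    """Extract a ``size`` × ``size`` patch centered on a keypoint.

    The window is clamped inside the frame when the keypoint is within
    ``size/2`` of a border, so the output shape is always (size, size, ...).
    Frames smaller than ``size`` are zero-padded symmetrically.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    if isinstance(center, Keypoint):
        if center.visible == KP_ABSENT:
            raise ValueError("keypoint is absent; caller must fall back to full body")
        cx, cy = center.x, center.y
    else:
        cx, cy = center
    H, W = frame.shape[:2]
    if H < 1 or W < 1:
        raise ValueError("frame must be at least 1x1")

    extra = frame.shape[2:]
    out = np.zeros((size, size) + extra, dtype=frame.dtype)

    # pad axes independently: center what fits, clamp what does not
    def _span(c: float, n: int) -> tuple[int, int, int]:
        """source start, source stop, destination start along one axis"""
        if n >= size:
            start = int(round(c)) - size // 2
            start = min(max(start, 0), n - size)
            return start, start + size, 0
        dst = (size - n) // 2
        return 0, n, dst

    sx0, sx1, dx = _span(cx, W)
    sy0, sy1, dy = _span(cy, H)
    out[dy : dy + (sy1 - sy0), dx : dx + (sx1 - sx0)] = frame[sy0:sy1, sx0:sx1]
    return out


def sample_two_stream_frames(n_frames: int, T: int, tau: int, alpha: int
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Frame indices for the two pathways.

    The slow pathway takes ``T`` frames with stride ``tau``, offset-centered
    in the clip; the fast pathway takes ``alpha*T`` frames uniformly spaced
    over the same window.
    """
    needed = T * tau
    if n_frames < needed:
        raise ValueError(f"clip has {n_frames} frames but T*tau={needed} are required")
    span = (T - 1) * tau
    offset = (n_frames - 1 - span) // 2
    slow = offset + tau * np.arange(T)
    fast = np.round(np.linspace(slow[0], slow[-1], alpha * T)).astype(int)
    return slow, fast


def _square_box(box: BoundingBox, H: int, W: int) -> tuple[int, int, int, int]:
    """Expand a box to a square (side = max extent), clamped to the frame."""
    side = max(box.width, box.height)
    cx, cy = box.center
    x0 = int(round(cx - side / 2))
    y0 = int(round(cy - side / 2))
    s = int(round(side))
    s = max(s, 2)
    x0 = min(max(x0, 0), max(W - s, 0))
    y0 = min(max(y0, 0), max(H - s, 0))
    return x0, y0, min(x0 + s, W), min(y0 + s, H)


def _to_unit(frames: np.ndarray) -> np.ndarray:
    """uint8 frames -> centered float32 in [-0.5, 0.5] (0 = neutral gray)."""
    f = frames.astype(np.float32)
    return f / 255.0 - 0.5 if frames.dtype == np.uint8 else f


def _resize_stack(stack: np.ndarray, out_hw: int) -> np.ndarray:
    out = np.empty((stack.shape[0], out_hw, out_hw, stack.shape[3]), dtype=np.float32)
    for i, fr in enumerate(stack):
        if fr.shape[0] == out_hw and fr.shape[1] == out_hw:
            out[i] = fr
        else:
            out[i] = resize(fr, (out_hw, out_hw), order=1, anti_aliasing=False,
                            preserve_range=True)
    return out


def extract_pathway_frames(
    frames: np.ndarray,
    indices: np.ndarray,
    content: str,
    body_box: BoundingBox,
    mouth: Keypoint | None,
    crop_size: int,
    out_res: int,
) -> np.ndarray:
    """Cut either full-body squares or mouth patches at given frame indices."""
    H, W = frames.shape[1:3]
    if content == MOUTH_CROP:
        if mouth is None or mouth.visible == KP_ABSENT:
            raise ValueError("mouth crop requested but keypoint is absent")
        stack = np.stack([crop_region(frames[i], mouth, crop_size) for i in indices])
    else:
        if body_box.width < 2 or body_box.height < 2:
            raise ValueError(f"degenerate body box {body_box}")
        x0, y0, x1, y1 = _square_box(body_box, H, W)
        stack = np.stack([frames[i, y0:y1, x0:x1] for i in indices])
    return _resize_stack(_to_unit(stack), out_res)


def route_inputs(
    clip_frames: np.ndarray,
    body_box: BoundingBox,
    mouth_kp: Keypoint | None,
    label_hint: int | str | None,
    scheme: str,
    config: PipelineConfig,
    slow_res: int = 32,
    fast_res: int = 32,
    clip_id: str = "",
) -> TwoStreamInput:
    """Build the routed TwoStreamInput for one sample.

    ``label_hint`` is the ground-truth label in training mode and ``None`` at
    inference. The mouth substitution of schemes B/C is applied when
    (training) the label is licking and the keypoint is visible, or
    (inference) whenever the keypoint is visible.
    """
    if scheme not in ("A", "B", "C"):
        raise ValueError(f"unknown routing scheme {scheme!r}")
    if isinstance(label_hint, str):
        label_hint = BEHAVIOR_TO_ACTION_ID[label_hint]

    slow_idx, fast_idx = sample_two_stream_frames(
        clip_frames.shape[0], config.T, config.tau, config.alpha
    )

    mouth_ok = mouth_kp is not None and mouth_kp.visible != KP_ABSENT
    if label_hint is None:
        use_crop = mouth_ok and scheme != "A"
    else:
        use_crop = (
            scheme != "A"
            and label_hint == BEHAVIOR_TO_ACTION_ID["licking"]
            and mouth_ok
        )

    slow_content = MOUTH_CROP if (use_crop and scheme == "C") else FULL_BODY
    fast_content = MOUTH_CROP if (use_crop and scheme == "B") else FULL_BODY

    slow = extract_pathway_frames(clip_frames, slow_idx, slow_content, body_box,
                                  mouth_kp, config.crop_size, slow_res)
    fast = extract_pathway_frames(clip_frames, fast_idx, fast_content, body_box,
                                  mouth_kp, config.crop_size, fast_res)
    return TwoStreamInput(slow_frames=slow, fast_frames=fast, scheme=scheme,
                          clip_id=clip_id, slow_content=slow_content,
                          fast_content=fast_content)
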