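"""Readers and writers for the pipeline's on-disk formats, plus dataset splitting.

Formats:

* AVA-style behavior CSV — 8 comma-separated fields per row:
  ``video_id, timestamp_s, x1, y1, x2, y2, action_id, entity_id`` with box
  coordinates normalized to [0, 1] by frame width/height.
* Detection stream — JSON lines, one object per detection with
  ``frame_index``, ``box`` (pixel [x1,y1,x2,y2]), ``score`` and ``mouth``
  ({x, y, visible}).
* Frame directories of ``frame_%06d.png`` images (MP4 is read through
  imageio when a decoder plugin is present).
* YAML pipeline configuration mirroring :class:`~satsn.datamodel.PipelineConfig`.

All writers are deterministic: identical inputs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .datamodel import (
    KP_ABSENT,
    AvaRecord,
    BoundingBox,
    Detection,
    Keypoint,
    PipelineConfig,
    TrainingConfig,
    VideoClip,
)

logger = logging.getLogger(__name__)

AVA_N_FIELDS = 8


class ParseError(ValueError):
    """Raised when an input file violates the format contract; names the row."""


def _fmt_float(v: float) -> str:
    """Shortest round-trippable decimal representation (bit-exact round trips)."""
    return repr(float(v))


# ---------------------------------------------------------------------------
# AVA CSV
# ---------------------------------------------------------------------------

def read_ava_csv(path: str | os.PathLike) -> list[AvaRecord]:
    """Parse an AVA-format behavior CSV into records.

    Malformed rows (wrong field count, non-numeric values, coordinates outside
    [0,1], x1>=x2 / y1>=y2, unknown action id) raise :class:`ParseError`
    naming the offending line number; nothing is silently coerced.
    """
    records: list[AvaRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != AVA_N_FIELDS:
                raise ParseError(
                    f"{path}: line {lineno}: expected {AVA_N_FIELDS} fields, got {len(fields)}"
                )
            try:
                rec = AvaRecord(
                    video_id=fields[0],
                    timestamp_s=int(fields[1]),
                    box_norm=tuple(float(v) for v in fields[2:6]),  # type: ignore[arg-type]
                    action_id=int(fields[6]),
                    entity_id=int(fields[7]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_ava_csv(records: Iterable[AvaRecord], path: str | os.PathLike) -> None:
    """Write records as AVA CSV; ``read_ava_csv`` round-trips bit-exactly."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in records:
            x1, y1, x2, y2 = r.box_norm
            fh.write(
                ",".join(
                    [
                        r.video_id,
                        str(r.timestamp_s),
                        _fmt_float(x1),
                        _fmt_float(y1),
                        _fmt_float(x2),
                        _fmt_float(y2),
                        str(r.action_id),
                        str(r.entity_id),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Detection stream (JSON lines)
# ---------------------------------------------------------------------------

def _detection_to_obj(d: Detection) -> dict:
    obj: dict = {
        "frame_index": d.frame_index,
        "box": [d.box.x1, d.box.y1, d.box.x2, d.box.y2],
        "score": d.score,
        "mouth": {"x": d.mouth.x, "y": d.mouth.y, "visible": d.mouth.visible},
    }
    if d.gt_id is not None:
        obj["gt_id"] = d.gt_id
    return obj


def write_detection_stream(dets: Iterable[Detection], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for d in dets:
            fh.write(json.dumps(_detection_to_obj(d), sort_keys=True) + "\n")


def read_detection_stream(path: str | os.PathLike) -> list[Detection]:
    """Read a JSON-lines detection stream, returned sorted by frame index.

    A detection without a ``mouth`` field is accepted with ``visible=0``
    (coordinates ignored downstream) and logged as a warning.
    """
    dets: list[Detection] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: line {lineno}: invalid JSON: {exc}") from exc
            try:
                if "mouth" in obj:
                    m = obj["mouth"]
                    mouth = Keypoint(float(m["x"]), float(m["y"]), int(m["visible"]))
                else:
                    logger.warning("%s: line %d: missing mouth field; marked absent", path, lineno)
                    mouth = Keypoint(0.0, 0.0, KP_ABSENT)
                dets.append(
                    Detection(
                        frame_index=int(obj["frame_index"]),
                        box=BoundingBox.from_array(obj["box"]),
                        score=float(obj["score"]),
                        mouth=mouth,
                        gt_id=int(obj["gt_id"]) if "gt_id" in obj else None,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    dets.sort(key=lambda d: d.frame_index)
    return dets


def group_by_frame(dets: Sequence[Detection]) -> dict[int, list[Detection]]:
    """Group a detection stream into per-frame lists (keys sorted ascending)."""
    out: dict[int, list[Detection]] = {}
    for d in sorted(dets, key=lambda d: d.frame_index):
        out.setdefault(d.frame_index, []).append(d)
    return out


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------

def split_dataset(
    item_ids: Sequence, ratios: Sequence[float], seed: int
) -> list[list]:
    """Split items into disjoint partitions with floor-allocated sizes.

    Ratios are normalized to sum to 1; each partition gets
    ``floor(n * ratio)`` items and the remainder goes to the first partition,
    so an 8:1:1 split of 2200 items yields 1760/220/220 and an 8:2 split of
    420 yields 336/84. Items are shuffled with the given seed before slicing.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("need at least one ratio")
    if np.any(ratios < 0):
        raise ValueError(f"ratios must be nonnegative, got {ratios.tolist()}")
    total = ratios.sum()
    if total <= 0:
        raise ValueError("ratios must sum to a positive value")
    ratios = ratios / total

    items = list(item_ids)
    n = len(items)
    sizes = [int(np.floor(n * r)) for r in ratios]
    sizes[0] += n - sum(sizes)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [items[i] for i in order]
    parts: list[list] = []
    start = 0
    for s in sizes:
        parts.append(shuffled[start : start + s])
        start += s
    return parts


# ---------------------------------------------------------------------------
# Frames / clips
# ---------------------------------------------------------------------------

FRAME_NAME = "frame_%06d.png"
_FRAME_RE = re.compile(r"frame_(\d{6})\.(png|jpg|jpeg)$", re.IGNORECASE)


def write_frame_dir(clip: VideoClip, out_dir: str | os.PathLike) -> None:
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(clip.frames):
        iio.imwrite(out / (FRAME_NAME % i), frame)


def load_clip(path: str | os.PathLike, clip_id: str | None = None, fps: float = 30.0) -> VideoClip:
    """Load a clip from a frame directory (``frame_%06d.png``) or an MP4 file."""
    import imageio.v3 as iio

    p = Path(path)
    if p.is_dir():
        entries = sorted(
            (int(m.group(1)), f)
            for f in os.listdir(p)
            if (m := _FRAME_RE.match(f))
        )
        if not entries:
            raise FileNotFoundError(f"no frame_XXXXXX images in {p}")
        frames = np.stack([iio.imread(p / f) for _, f in entries])
    else:
        frames = np.stack(list(iio.imiter(p)))
    return VideoClip(clip_id=clip_id or p.stem, frames=frames, fps=fps)


# ---------------------------------------------------------------------------
# MOT-challenge CSV (tracker output)
# ---------------------------------------------------------------------------

MOT_HEADER = "frame,id,x,y,w,h,score"


def write_mot_csv(rows: Iterable[tuple[int, int, float, float, float, float, float]],
                  path: str | os.PathLike) -> None:
    """Write per-frame track boxes as ``frame,id,x,y,w,h,score`` rows."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(MOT_HEADER + "\n")
        for frame, tid, x, y, w, h, score in rows:
            fh.write(
                f"{frame},{tid},{_fmt_float(x)},{_fmt_float(y)},"
                f"{_fmt_float(w)},{_fmt_float(h)},{_fmt_float(score)}\n"
            )


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def load_config(path: str | os.PathLike) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    training = TrainingConfig(**data.pop("training", {}))
    return PipelineConfig(training=training, **data)


def save_config(config: PipelineConfig, path: str | os.PathLike) -> None:
    data = dataclasses.asdict(config)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
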