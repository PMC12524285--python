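"""The spatial-adaptive two-stream network.

Slow pathway: non-overlapping tubelet tokens (t×h×w patches linearly embedded
with learned positional embeddings) passed through pre-norm transformer
blocks with joint space-time attention. Fast pathway: a stack of 3D
convolution stages over the alpha-times-denser frame stream, with a reduced
(beta-scaled) channel budget, spatial downsampling by 2 per stage, no
temporal downsampling, and a temporal-attention block after each stage.
Stage outputs are laterally fused into the slow tokens (temporal stride
alpha, spatial average-pooling to the token grid, learned linear projection,
additive). The head concatenates mean-pooled slow tokens with globally
pooled final fast features and applies a linear + softmax 4-class classifier.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._autograd import Tensor, concat
from .nn import (SGD, Conv3d, LayerNorm, Linear, Module, TransformerBlock,
                 cross_entropy, parameter)
from .temporal_attention import TemporalAttention

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SatsnArchConfig:
    """Architecture hyperparameters; the parameter count is a pure function of these."""

    T: int = 4                     # slow-pathway frame count
    alpha: int = 4                 # fast/slow frame-rate ratio
    slow_res: int = 32
    fast_res: int = 32
    tubelet: tuple[int, int, int] = (2, 8, 8)   # (t, h, w)
    embed_dim: int = 64
    vit_depth: int = 2
    n_heads: int = 4
    mlp_ratio: float = 2.0
    fast_channels: tuple[int, ...] = (8, 16)    # beta-scaled channel plan
    fast_kernel: tuple[int, int, int] = (3, 3, 3)
    lateral_after: tuple[int, ...] = (1, 2)     # fuse after these ViT blocks (1-based)
    ta_r: int = 2
    ta_per_stage: bool = True
    num_classes: int = 4

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if len(self.lateral_after) != len(self.fast_channels):
            raise ValueError("need one lateral fusion point per fast stage")
        tt, th, tw = self.tubelet
        if self.T % tt or self.slow_res % th or self.slow_res % tw:
            raise ValueError(
                f"slow input (T={self.T}, res={self.slow_res}) not divisible by "
                f"tubelet {self.tubelet}; pad or change the tubelet size"
            )
        fr = self.fast_res
        for _ in self.fast_channels:
            if fr % 2:
                raise ValueError("fast_res too small for the configured stage count")
            fr //= 2
        gh = self.slow_res // th
        if fr % gh:
            raise ValueError("final fast feature map does not pool onto the token grid")

    @property
    def token_grid(self) -> tuple[int, int, int]:
        tt, th, tw = self.tubelet
        return (self.T // tt, self.slow_res // th, self.slow_res // tw)

    @property
    def n_tokens(self) -> int:
        t, h, w = self.token_grid
        return t * h * w


#: desk-scale profile used by the synthetic-recovery experiments
TINY = SatsnArchConfig()


class SatsnModel(Module):
    """All learnable parameters of the two-stream network."""

    def __init__(self, config: SatsnArchConfig, seed: int = 0,
                 dtype=np.float32):
        self.config = config
        self.seed = seed
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        tt, th, tw = config.tubelet
        patch_dim = tt * th * tw * 3
        self.patch_proj = Linear(patch_dim, config.embed_dim, rng)
        self.pos_emb = parameter(rng.normal(0.0, 0.02,
                                            size=(config.n_tokens, config.embed_dim)))
        self.blocks = [TransformerBlock(config.embed_dim, config.n_heads, rng,
                                        config.mlp_ratio)
                       for _ in range(config.vit_depth)]
        c_in = 3
        self.fast_convs: list[Conv3d] = []
        self.ta_blocks: list[TemporalAttention] = []
        self.laterals: list[Linear] = []
        for c_out in config.fast_channels:
            self.fast_convs.append(Conv3d(c_in, c_out, config.fast_kernel, rng,
                                          stride=(1, 2, 2)))
            self.ta_blocks.append(TemporalAttention(config.T * config.alpha,
                                                    config.ta_r, rng))
            self.laterals.append(Linear(c_out, config.embed_dim, rng, bias=False))
            c_in = c_out
        head_in = config.embed_dim + config.fast_channels[-1]
        self.head_norm = LayerNorm(head_in)
        self.head = Linear(head_in, config.num_classes, rng)
        # zero-init classifier: initial predictions are exactly uniform
        self.head.weight.data[:] = 0.0
        for p in self.parameters():
            p.data = p.data.astype(self.dtype)

    # -- slow pathway -------------------------------------------------------
    def tubelet_embed(self, slow_frames: np.ndarray | Tensor) -> Tensor:
        """(B, T, H, W, 3) frames -> (B, N, D) tokens with positional embeddings."""
        x = slow_frames if isinstance(slow_frames, Tensor) \
            else Tensor(np.asarray(slow_frames, dtype=self.dtype))
        B, T, H, W, C = x.shape
        tt, th, tw = self.config.tubelet
        if T % tt or H % th or W % tw:
            raise ValueError(
                f"input ({T},{H},{W}) not divisible by tubelet ({tt},{th},{tw}); "
                f"pad to multiples of the tubelet size"
            )
        gt, gh, gw = T // tt, H // th, W // tw
        x = x.reshape(B, gt, tt, gh, th, gw, tw, C)
        x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)          # (B, gt, gh, gw, tt, th, tw, C)
        x = x.reshape(B, gt * gh * gw, tt * th * tw * C)
        return self.patch_proj(x) + self.pos_emb

    def vit_encode(self, tokens: Tensor, depth: int | None = None) -> Tensor:
        """Run (a prefix of) the transformer blocks; depth 0 is the identity."""
        n = self.config.vit_depth if depth is None else depth
        for block in self.blocks[:n]:
            tokens = block(tokens)
        return tokens

    # -- fast pathway -------------------------------------------------------
    def fast_pathway(self, fast_frames: np.ndarray | Tensor,
                     apply_ta: bool = True) -> list[Tensor]:
        """(B, alpha*T, h, w, 3) frames -> per-stage (B, T_f, C_s, H_s, W_s) features."""
        x = fast_frames if isinstance(fast_frames, Tensor) \
            else Tensor(np.asarray(fast_frames, dtype=self.dtype))
        B, Tf, H, W, C = x.shape
        if H < 2 ** len(self.config.fast_channels):
            raise ValueError("fast input smaller than the total spatial downsampling")
        x = x.transpose(0, 4, 1, 2, 3)                   # (B, C, T, H, W)
        feats: list[Tensor] = []
        for conv, ta in zip(self.fast_convs, self.ta_blocks):
            x = conv(x).relu()
            f = x.transpose(0, 2, 1, 3, 4)               # (B, T, C, H, W)
            if apply_ta and self.config.ta_per_stage:
                f = ta(f)
            feats.append(f)
            x = f.transpose(0, 2, 1, 3, 4)
        return feats

    # -- fusion -------------------------------------------------------------
    def lateral_fuse(self, fast_feat: Tensor, tokens: Tensor, stage_index: int) -> Tensor:
        """Stride-alpha subsample, pool to the token grid, project, add."""
        cfg = self.config
        gt, gh, gw = cfg.token_grid
        B, Tf, Cs, Hs, Ws = fast_feat.shape
        idx = np.arange(0, Tf, cfg.alpha)                # T slow-aligned frames
        f = fast_feat.index_select(1, idx)               # (B, T, C, H, W)
        tt = cfg.tubelet[0]
        f = f.reshape(B, gt, tt, Cs, Hs, Ws).mean(axis=2)
        if Hs % gh or Ws % gw:
            raise ValueError(f"fast grid ({Hs},{Ws}) does not pool onto token grid ({gh},{gw})")
        f = f.reshape(B, gt, Cs, gh, Hs // gh, gw, Ws // gw).mean(axis=(4, 6))
        f = f.transpose(0, 1, 3, 4, 2).reshape(B, gt * gh * gw, Cs)
        return tokens + self.laterals[stage_index](f)

    # -- full forward -------------------------------------------------------
    def forward_logits(self, slow_frames: np.ndarray | Tensor,
                       fast_frames: np.ndarray | Tensor) -> Tensor:
        tokens = self.tubelet_embed(slow_frames)
        feats = self.fast_pathway(fast_frames)
        fusion_at = {blk: i for i, blk in enumerate(self.config.lateral_after)}
        for i, block in enumerate(self.blocks, start=1):
            tokens = block(tokens)
            if i in fusion_at:
                tokens = self.lateral_fuse(feats[fusion_at[i]], tokens, fusion_at[i])
        slow_vec = tokens.mean(axis=1)                   # (B, D)
        fast_vec = feats[-1].mean(axis=(1, 3, 4))        # (B, C_last)
        return self.head(self.head_norm(concat([slow_vec, fast_vec], axis=-1)))

    def forward(self, slow_frames: np.ndarray | Tensor,
                fast_frames: np.ndarray | Tensor) -> Tensor:
        """Class probabilities (B, num_classes); deterministic in eval mode."""
        return self.forward_logits(slow_frames, fast_frames).softmax(axis=-1)

    def predict_proba(self, slow_frames: np.ndarray, fast_frames: np.ndarray) -> np.ndarray:
        return self.forward(slow_frames, fast_frames).data


def satsn_forward(two_stream_input, model: SatsnModel) -> np.ndarray:
    """Probabilities (length num_classes) for one routed sample."""
    return model.predict_proba(two_stream_input.slow_frames[None],
                               two_stream_input.fast_frames[None])[0]


def count_parameters(config: SatsnArchConfig) -> int:
    """Parameter count as a pure function of the architecture config."""
    return SatsnModel(config, seed=0).n_parameters()


# ---------------------------------------------------------------------------
# Augmentation (training only; identical transform for both pathways)
# ---------------------------------------------------------------------------

def augment_sample(slow: np.ndarray, fast: np.ndarray, rng: np.random.Generator,
                   max_rot_deg: float = 15.0) -> tuple[np.ndarray, np.ndarray]:
    """Rotation (<= 15 deg), horizontal flip, brightness/contrast jitter.

    One transform is drawn per sample and applied to every frame of both
    pathways so the two streams stay geometrically consistent.
    """
    flip = rng.uniform() < 0.5
    angle = float(rng.uniform(-max_rot_deg, max_rot_deg))
    gain = float(rng.uniform(0.85, 1.15))
    offset = float(rng.uniform(-0.08, 0.08))

    def tf(stack: np.ndarray) -> np.ndarray:
        out = stack[:, :, ::-1] if flip else stack
        if abs(angle) > 0.5:
            out = ndimage.rotate(out, angle, axes=(2, 1), reshape=False,
                                 order=1, mode="nearest")
        return np.clip(out * gain + offset, -0.5, 0.5)

    return tf(slow), tf(fast)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_satsn(
    dataset: list[tuple[np.ndarray, np.ndarray, int]],
    arch: SatsnArchConfig = TINY,
    seed: int = 0,
    epochs: int = 200,
    batch_size: int = 4,
    learning_rate: float = 0.02,
    momentum: float = 0.9,
    augment: bool = True,
    warmup_epochs: int = 2,
    cosine_decay: bool = True,
    restarts: int = 1,
    restart_loss_target: float = 0.3,
) -> tuple[SatsnModel, list[dict]]:
    """SGD-with-momentum training; reproducible loss curve for a fixed seed.

    ``dataset`` yields (slow_frames, fast_frames, label) triples as produced
    by the ROI router. The learning rate ramps linearly over the warmup
    epochs and then follows a cosine decay to a tenth of its peak.

    Training a small transformer from scratch with plain SGD is sensitive to
    the initialization draw, so ``restarts > 1`` reruns the fit from
    deterministically derived seeds until the final *training* loss falls
    below ``restart_loss_target`` (the best attempt by training loss is kept;
    no held-out information is consulted). Raises on an empty dataset and
    aborts with diagnostics if the loss goes non-finite.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    best: tuple[SatsnModel, list[dict]] | None = None
    for attempt in range(max(restarts, 1)):
        attempt_seed = (seed + 9973 * attempt) % (2**31 - 1)
        model, log = _train_once(
            dataset, arch, attempt_seed, epochs, batch_size, learning_rate,
            momentum, augment, warmup_epochs, cosine_decay)
        if best is None or log[-1]["loss"] < best[1][-1]["loss"]:
            best = (model, log)
        if best[1][-1]["loss"] <= restart_loss_target:
            break
        if attempt + 1 < max(restarts, 1):
            logger.info("restarting training: final loss %.4f above target %.2f",
                        log[-1]["loss"], restart_loss_target)
    return best


def _train_once(dataset, arch, seed, epochs, batch_size, learning_rate,
                momentum, augment, warmup_epochs, cosine_decay
                ) -> tuple[SatsnModel, list[dict]]:
    model = SatsnModel(arch, seed=seed)
    opt = SGD(model.parameters(), lr=learning_rate, momentum=momentum)
    rng = np.random.default_rng(seed + 1)
    log: list[dict] = []
    n = len(dataset)
    for epoch in range(epochs):
        if warmup_epochs and epoch < warmup_epochs:
            lr = learning_rate * (epoch + 1) / warmup_epochs
        elif cosine_decay and epochs > warmup_epochs:
            frac = (epoch - warmup_epochs) / max(epochs - warmup_epochs, 1)
            lr = learning_rate * (0.1 + 0.9 * 0.5 * (1 + math.cos(math.pi * frac)))
        else:
            lr = learning_rate
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            slows, fasts, labels = [], [], []
            for i in idx:
                s, f, y = dataset[i]
                if augment:
                    s, f = augment_sample(s, f, rng)
                slows.append(s)
                fasts.append(f)
                labels.append(y)
            logits = model.forward_logits(np.stack(slows), np.stack(fasts))
            loss = cross_entropy(logits, np.asarray(labels))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {start // batch_size}: "
                    f"loss={loss.data!r}; last lr={lr}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.append({"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr})
        logger.debug("epoch %d: loss %.4f", epoch, log[-1]["loss"])
    return model, log


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: SatsnModel, path: str | os.PathLike) -> None:
    header = json.dumps({
        "version": CHECKPOINT_VERSION,
        "config": dataclasses.asdict(model.config),
        "seed": model.seed,
    })
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, header=np.array(header), **arrays)


def load_checkpoint(path: str | os.PathLike,
                    expect_config: SatsnArchConfig | None = None) -> SatsnModel:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        cfg_dict = header["config"]
        for key in ("tubelet", "fast_channels", "fast_kernel", "lateral_after"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = SatsnArchConfig(**cfg_dict)
        if expect_config is not None and config != expect_config:
            raise ValueError(
                f"checkpoint config {config} does not match expected {expect_config}"
            )
        model = SatsnModel(config, seed=header.get("seed", 0))
        n = len(model.parameters())
        model.load_state_arrays([data[f"p{i}"] for i in range(n)])
    return model


def write_training_log(log: list[dict], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("epoch,loss,lr\n")
        for row in log:
            fh.write(f"{row['epoch']},{row['loss']!r},{row['lr']!r}\n")
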