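# Methods

This note records the models implemented in `satsn`, the parameters that
matter, what the synthetic scenes do and do not emulate, and the numerical
and design choices made where the design was genuinely open.

## Two-stream classification model

**Slow pathway.** `T` frames sampled with temporal stride `τ`,
offset-centered in the clip, are resized to `slow_res²`, cut into
non-overlapping `t×h×w` tubelets, linearly projected to `embed_dim`, and
summed with learned positional embeddings. Pre-norm transformer blocks with
joint space-time attention (every token attends to all tokens across space
and time) encode the sequence. Depth-0 encoding is the identity; attention
rows sum to one by construction.

**Fast pathway.** `αT` frames (α times denser over the same temporal
window) pass through a stack of 3D-convolution stages with 'same' padding,
stride (1, 2, 2) — no temporal downsampling, spatial halving per stage —
and a channel plan scaled by `β` relative to the slow embedding width
(default plan (8, 16) against `embed_dim` 64, i.e. β = 1/8). A temporal
attention block follows every stage (a switch can restrict it to the last).

**Temporal attention.** Per frame, features are average- and max-pooled
over (C, H, W) to two length-`T` descriptors; both pass the shared
bottleneck `W_m ReLU(W_n ·)` with reduction ratio `r` (default 2, must
divide the fast frame count), are summed and squashed by a sigmoid into
weights `M ∈ (0,1)^T` that rescale the frames. Choices worth flagging:

- the squashing function is a sigmoid — implied by the module's channel-
  attention lineage and by `M` being called a weight in (0,1);
- pooling preserves the temporal axis (pooling it away would make a
  length-`T` weight vector impossible);
- the bottleneck is applied reduction-first (`W_n` then `W_m`), and the
  printed weight dimensions are read to match that order;
- no bias terms, so the all-zero-weight module multiplies features by
  exactly σ(0) = ½ — a closed form the unit tests pin;
- the reweighting is pure (no residual around it); a residual variant would
  bias weights toward 1.5× instead and is easy to add if wanted.

**Lateral fusion.** After configured ViT blocks (defaults: blocks 1 and 2
for depth 2), the matching fast-stage output is temporally subsampled by
stride α, mean-pooled temporally onto the token-grid's temporal extent and
spatially onto its spatial extent, linearly projected (no bias) to
`embed_dim`, and added to the slow tokens. The zero-projection limit leaves
tokens untouched, and the projection path is linear — both are tested. This
"stride + pool + project + add" reading was chosen because the fusion
mechanics were otherwise unspecified; it is shape-sound and parameter-light,
in the spirit of stage-wise slow/fast laterals.

**Head.** Mean over slow tokens concatenated with the globally pooled final
fast features, layer-normalized, then a linear layer and softmax over the
four classes. The classifier weights start at zero so the initial
prediction is exactly uniform; with the centered inputs (below) this made
SGD training stable at the configured learning rates.

**Training.** SGD with momentum (full-scale defaults: batch 4, 200 epochs,
lr 0.02, momentum 0.9 — all overridable), cross-entropy loss (no loss was
otherwise prescribed), linear warmup over 2 epochs then cosine decay to a
tenth of peak lr. Augmentation (training only, identical across both
pathways of a sample): horizontal flip, rotation up to 15°, brightness /
contrast jitter. Routed frames are centered to [-0.5, 0.5]; all-positive
inputs measurably destabilized early training. Everything is driven by one
seed; two runs with the same seed produce identical checkpoints.

The network runs on an in-repo reverse-mode autodiff engine over numpy
(`satsn._autograd`) with float32 parameters; gradient correctness is pinned
by finite-difference tests. Training from scratch is the supported path;
externally pretrained weights can be injected through the `.npz` checkpoint
format (JSON config header + parameter arrays).

## Spatial-adaptive routing

Mouth crops are square windows centered on the mouth keypoint, clamped
inside the frame (clamping, not truncation, keeps the network input size
fixed) and zero-padded if the frame is smaller than the window. The
full-scale crop is 128 px, tied to 4K source frames; the desk-scale
experiments use 32 px crops on 160×256 scenes so the crop enters the 32²
network input at native resolution — not downscaling the mouth region is
the point of the cropping strategy — while the full-body view is downscaled
by roughly 2×. The full-body input is the detection box expanded to a square
and resized to the pathway resolution (the resize policy was unspecified;
square expansion avoids aspect distortion).

Scheme semantics: during training the mouth substitution applies only to
samples labeled licking; other classes use full-body inputs in both
pathways. At inference the labels do not exist and the label-conditional
rule is circular, so the router applies the scheme whenever the keypoint is
visible (falling back to full-body otherwise) and records the decision. A
two-pass alternative (classify under scheme A, re-route licking candidates
under scheme B) can be built from the same primitives.

The routing resolutions for the desk profile are slow 32², fast 32². An
optional extra downscale of full-body fast inputs (suggested by the
efficiency argument for the routing strategy) is deliberately not applied
by default; `fast_res` is simply configurable.

## Observation-centric tracking

State `[cx, cy, s, r, vcx, vcy, vs]` (center, box area, aspect ratio,
velocities; aspect held constant) with a constant-velocity transition and
SORT-style diagonal noise (`Q` velocity terms ×0.01, `R` area/aspect terms
×10, both scalable). Covariances are symmetrized every step and stay PSD
over thousands of random steps in tests.

- **Association (OCM).** Cost `= (1 − IoU(predicted, det)) + λ·θ/π`, where
  θ is the angle between the observation-derived track direction (centers
  `Δt` observed frames apart) and the last-observation→candidate direction.
  The direction term uses observations, not filter states. The momentum
  cost's second argument as printed collapses to a self-comparison; it is
  implemented as this angle consistency per the surrounding prose, with θ
  normalized by π so λ is scale-free. Tracks with < Δt+1 observations, or
  zero-length directions, contribute zero momentum cost. Assignment is
  minimum-cost bipartite (Hungarian) with pairs under `iou_min` rejected
  afterwards and ties broken deterministically by index.
- **Recovery (OCR).** Unmatched tracks' *last observations* are greedily
  re-matched to unmatched detections by GIoU ≥ `ocr_giou_min`.
- **Re-update (ORU).** On re-activation after a gap, the filter rolls back
  to the stored posterior at the last real observation and re-runs
  predict/update along the linear virtual trajectory between the last and
  the new observation. A one-frame gap reduces exactly to a plain update;
  for longer gaps the post-ORU covariance trace is strictly below coasting.

Defaults (`λ = 0.2, Δt = 3, iou_min = 0.3, max_age = 30, min_hits = 3,
ocr_giou_min = −0.2`) are this package's choices — the source method names
none — and all sit in `TrackerConfig`.

## Evaluation protocol

Keyframe evaluation at 1 Hz: per class, predictions are matched to
ground-truth boxes greedily in confidence-descending order at IoU ≥ 0.5
(configurable), each ground truth matched at most once. AP is the area
under the all-point interpolated precision-recall curve; mAP the plain mean
over classes with defined AP (classes without ground truth are excluded
with a warning). Zero-denominator precision/recall return 0 by convention
(logged). Operating-point P/R/F1 are reported alongside AP because the
published operating points cannot be reconstructed from a PR curve alone.
An *event* in the ethogram statistics is a maximal single-label run of at
least `min_event_s` (default 1 s) — the source quantifies event counts
without defining an event, so the threshold is explicit and configurable.

## Synthetic scenes

Fixed camera, static textured background, a vertical tree trunk, a feeding
trough, and agents rendered as textured body ellipses with neck and head
appendages (pure array composition — no graphics stack). Behavior
signatures: walking translates the body ≥ 2 px/frame; standing is static
(≤ 0.2 px/frame) with the head up; eating lowers the head into the trough
band with a slow (0.07 cycles/frame) large-amplitude mouth oscillation;
licking holds the body static with the mouth in contact with the trunk and
a fast (0.40 cycles/frame) small-amplitude oscillation plus an intermittent
tongue patch. Half of the standing agents take a *near-tree investigative
pose* — licking-like geometry with the mouth resting 2–5 px short of the
trunk, no oscillation, no tongue — so the licking class genuinely requires
mouth-region cues rather than gross position, mirroring the real confusion
between licking and standing near trees. The gap sits at or below the pixel
scale of the roughly 2×-downscaled full-body view, while a
native-resolution mouth crop sees both the gap and, decisively, the
presence or absence of the blinking tongue. Note that downscaling encodes
sub-pixel geometry in edge intensities rather than erasing it, so the
full-body baseline is degraded in signal-to-noise and learnability, not
denied the information outright — the crop-vs-full-body comparison is
therefore genuinely stochastic at desk scale, with the crop routing ahead
on average. A
threshold classifier on clean ground truth (displacement, mouth-tree
distance plus mouth-motion variance, trough membership) reaches ≥ 95 %,
guaranteeing the learning task is solvable at desk scale.

The detection emulator jitters box corners (σ = 1.5 px) and the keypoint
(σ = 1 px), drops detections inside occluder strips or at a 2 % miss rate,
and draws confidences uniformly from [0.5, 1] — moment tests confirm the
stated distributions. What the scenes do **not** emulate: photorealism,
articulated morphology, perspective, illumination change, inter-animal
occlusion during classification, or multi-species clutter. Passing the
desk-scale recovery therefore shows that the pipeline's machinery is
correct and that the routing exploits mouth-region signal when it is the
discriminative cue — not that the published real-data accuracies transfer.

## Desk-scale experiment sizes

The recovery experiment trains the tiny profile (embed 64, depth 2, slow
and fast at 32², tubelet (2, 8, 8)) on 200 balanced 64-frame 160×256 clips
(8:2 split) for 15 epochs at batch 4 and peak lr 0.02 (the published
training hyperparameters, epochs scaled down); the routing comparison
trains schemes A and B on matched 96-clip sets for 15 epochs across three
seeds, scores both on a shared independent 80-clip evaluation set per seed
(a larger held-out set keeps per-class AP ranking noise small), and
compares mean licking AP. With three seeds the comparison remains a
stochastic check: a single imperfectly converged model can still tilt one
seed's mean, so individual reruns with other seeds can occasionally order
the two schemes the other way. Training a small transformer from
scratch with plain SGD is sensitive to the initialization draw, so the
optimizer clips the global gradient norm at 5 and the experiments allow up
to three restarts from deterministically derived seeds, keeping the attempt
with the lowest final *training* loss (no held-out data is consulted). These sizes are the package's chosen
desk-scale study conditions; the full-scale defaults remain in the configs.
Held-out AP is computed at the clip level: every held-out clip contributes
its ground-truth box once per class with the model's class probability as
the score.

## Known limitations

- The tubelet grid requires input dimensions divisible by the tubelet and
  the final fast feature map must pool onto the token grid; violations
  raise with the required padding stated.
- The inference-time routing mismatch (training substitutes crops only for
  licking; inference crops whenever the keypoint is visible) is inherited
  from the method's design and handled by the network in practice, but a
  distribution gap remains by construction.
- The tracker has no appearance model; identity through long occlusions
  rests entirely on motion and the observation-centric mechanisms.
- MP4 reading depends on an imageio decoder plugin; frame directories are
  the first-class clip format.
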