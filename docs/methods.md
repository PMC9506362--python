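# Methods

This note documents the models, procedures and design choices behind the
package: what is computed, under which assumptions, and what the synthetic
studies do and do not demonstrate.

## Problem setting

The package works on skeleton-sequence gait data: a pose tracker watches
video and emits, per tracked person, a sequence of 18-keypoint planar
skeletons (COCO/OpenPose-18 layout) with a confidence per joint, a
bounding box and a stream frame rate. Downstream tasks are identity
recognition (gallery/probe rank-1), gender estimation and pedestrian-
attribute prediction — all from movement alone, never from appearance.
Each tracklet is treated as its own identity: real corpora built this way
have no cross-camera identity labels, which is exactly why contrastive
pretraining over augmented views of one tracklet is the supervisory
signal.

## Corpus construction

Tracker output is noisy; the construction pipeline applies, in order:

1. **Frame confidence filter** — frames whose mean joint confidence is
   below 0.5 are removed.
2. **Feet confidence filter** — frames whose mean ankle confidence is
   below 0.4 are removed; leg movement is the most informative signal and
   must be confidently detected.
3. **Duration filter** — tracklets shorter than `T * fps / 24` frames are
   dropped (T = 48 frames ≈ two gait cycles at the 24 FPS reference;
   the bound is computed in source-FPS units, before resampling).
4. **Pace unification** — linear interpolation of every channel onto a
   24 FPS grid covering the same wall-clock span.
5. **Body-frame normalization** — per frame, with pelvis = midpoint of the
   hips:

       x' = (x - x_pelvis) / max(|x_Rshoulder - x_Lshoulder|, 1e-6)
       y' = (y - y_pelvis) / max(|y_neck - y_pelvis|, 1e-6)

   This removes position, height and body scale. Absolute values on both
   denominators keep image-style y-down data from flipping sign; frames
   with a collapsed denominator (near-frontal shoulder overlap) are
   flagged degenerate rather than silently divided by epsilon-noise.
   Confidences pass through untouched.
6. **Leg-speed keep-band** — sequences whose mean per-frame displacement
   of knees+ankles (normalized units) falls outside [0.0015, 0.09] are
   dropped: below the band people are standing, above it the tracker was
   glitching. "Below" is strict for every threshold: equality is kept.

Design choices where the procedure is underdetermined: the pelvis is not a
COCO-18 keypoint, so it is defined as the hip midpoint; "the legs" are
knees+ankles; the keep-band thresholds are sub-unit magnitudes, which only
make sense on normalized coordinates, so the speed filter runs after
normalization and resampling, while the duration filter runs before
resampling (its bound is expressed in source-FPS frames). Frame removal
can open interior gaps: gaps of at most 12 frames (0.5 s) are refilled by
linear interpolation, longer gaps split the tracklet into independent
segments, because pace-sensitive training must not see fabricated
continuity across long occlusions.

## Attribute annotation

Tracklets are annotated with 42 soft labels in 8 groups (gender, age
group, body type, viewpoint, carry conditions, clothing, footwear,
apparent action) by an ensemble of three pedestrian-attribute predictors
with different vocabularies (PA100k / PETA / RAP). Per tracklet: the crop
at every 48th frame is predicted k = 4 times under light augmentations
(flip, ±10° rotation, brightness/contrast jitter) and averaged; the three
source vocabularies are coalesced onto the 42-target schema (mean for
repeated measurements of the same concept, max where sources are
alternatives, with one inversion: PETA's Male → Female); crop-level
vectors are pooled with bounding-box-area weights, since larger (nearer)
crops are more reliable. Labels are kept soft — the appearance head is
trained by distillation, and rounding would discard calibration.

The full 42-target membership is not available anywhere as a
machine-readable table, so the schema ships as an explicit, versioned
YAML reconstruction whose loader
enforces completeness (42 targets, 8 non-empty groups, every source label
mapped or dropped). Users can substitute their own schema file. The
predictor interface is an arbitrary callable on an image crop; no
pretrained weights are shipped or required — tests use deterministic
mocks at the vector level.

## Encoder

Each normalized frame flattens to 54 values (18 × (x, y, confidence));
a learnable affine layer projects to d_model = 256; a learnable positional
table (length 48, added, not concatenated) injects order; a stack of
post-norm transformer encoder layers (8 heads, biases everywhere, ReLU
feed-forward, no dropout) is mean-pooled over time. Heads: embedding
256→256 (identity representation, l2-normalized at evaluation),
projection 256→128 (contrastive loss input), appearance 256→42 with a
sigmoid.

Stock depths are SM/MD/XL = 4/8/12 layers. With feed-forward width 512
the trainable-parameter totals are 2,244,266 / 4,352,682 / 6,461,098
(2.24M / 4.35M / 6.46M), the reference totals for this architecture
family; a feed-forward width of 256 — which one reading of the original
description suggests — is inconsistent with those totals (≈0.26M/layer
instead of ≈0.53M/layer), so 512 is the default and the width stays
configurable. The appearance head is attached to the final 256-d
embedding. Parameter totals are verified in tests against a closed-form
component inventory, not against another counter.

The tensor engine underneath is a small reverse-mode automatic
differentiation core over numpy arrays (`gaitformer.nn`), gradient-checked
against central finite differences through the full encoder and both
losses. Default compute dtype is float32; the gradient checks switch to
float64.

## Objectives and schedules

**Supervised contrastive loss** over a two-viewed batch: each tracklet
contributes two independent augmentations; for anchor i with positive set
P(i) (same tracklet) and candidates A(i) (everything but i),

    L = mean_i  -(1/|P(i)|) * sum_{p in P(i)}
          log[ exp(z_i·z_p / τ) / sum_{a in A(i)} exp(z_i·z_a / τ) ]

on l2-normalized 128-d projections with τ = 0.001. At this temperature
logits reach ±2000, so the implementation always subtracts the row
maximum over A(i) before exponentiation and excludes the self-similarity
*before* the exponential (its shifted logit is large and positive and
would overflow). The anchor aggregation is a mean; a batch of two views of
one tracklet scores exactly zero. A vectorized evaluation is tested to
1e-6 against a literal double-loop transcription.

**Appearance loss**: soft-label binary cross-entropy averaged over the 42
attributes and both views, with predictions clamped to [1e-7, 1-1e-7].
**Combined**: `L_total = L_supcon + λ·L_appearance`, λ = 0.5 ("multi-task"
mode); λ is not applied in contrastive-only mode and the appearance head
then receives no gradient at all (verified bit-exact in tests).

Augmentations, in order pace → crop → flip → jitter (pace changes length,
so it precedes the fixed crop): time rescale by a factor uniform in
[0.75, 1.5]; contiguous crop of 48 frames with uniform start; horizontal
flip with p = 0.5 that negates x and swaps left/right joint triplets
including confidences (a mirrored left joint *is* the right joint's
measurement); Gaussian jitter (σ = 0.005 normalized units) on coordinates
only. The pace-factor range and noise magnitude are package defaults —
the procedure's description names the transforms but not magnitudes.

Pretraining: Adam, batch of 1024 view-samples (= 512 tracklets × 2 views;
desk-scale runs shrink this), triangular cyclical learning rate
1e-4 → 1e-3 → 1e-4 with a 20-epoch period. Fine-tuning: layer-wise
learning-rate decay — task heads at lr₀, encoder layer j counting from the
top at lr₀·0.9^(j+1), input projection and positional table at the
smallest rate (0.9 is a package default; the scheme, not the factor, is
prescribed) — under a linear lr₀ = 1e-4 → 0 schedule across 200 epochs.

## Evaluation protocols

Direct transfer: deterministic center crop of 48 frames, one forward
pass, l2-normalized 256-d embedding, no test-time augmentation. Rank-1
recognition: nearest gallery embedding by cosine similarity (equivalent to
Euclidean ranking on the unit sphere; ties resolve to the first gallery
index). Cross-view protocol: each viewpoint in turn is the probe set, the
gallery is every other viewpoint; probes whose subject is absent from
their gallery are skipped with a warning and counted in a coverage
statistic. Gender: macro-averaged precision/recall/F1 at threshold 0.5
(macro is a package decision; the averaging convention is not stated
upstream, and the report header records it). Attributes: per-attribute
R² = 1 − SS_res/SS_tot against the soft labels; a zero-variance target is
reported as missing (NaN), never as 0.

## Synthetic walkers

The simulator is a test harness, not a biomechanical model. A walker is a
set of latent parameters — cadence (0.7–1.2 Hz), stride and arm-swing
amplitudes, torso height, shoulder/torso and leg/torso and head/torso
proportions, foot-clearance amplitude, pelvis bob, viewpoint azimuth,
phase, per-joint noise — driving coupled sinusoids: legs in anti-phase at
the cadence, arms counter-phased, pelvis bob at twice the cadence, a
forward lean in the walking direction, and viewpoint foreshortening that
scales horizontal motion amplitudes (by |sin θ|) at a different rate than
the static shoulder span. Confidences are Beta-distributed near 0.9;
bounding boxes come from joint extents. Nominal parameters are calibrated
so every construction filter passes (measured normalized leg speeds fall
in ≈0.01–0.05, well inside the keep-band). Planted-defect renders violate
exactly one filter each: too-short, low confidence, low feet confidence,
static (no limb motion), erratic (leg tracking glitches); the confidence
defects use Beta(4, 36) so the 0.5/0.4 thresholds bisect the classes with
astronomically small error probability.

Each walker's attributes come from a fixed deterministic map of its
latents. Two lessons from building it are worth recording:

* **Cadence is deliberately unlearnable.** The pace augmentation rescales
  time by 0.75–1.5× while labels stay fixed, so any attribute coded on
  gait frequency is unrecoverable *by construction of the training
  procedure itself* — an early version of the map did this and the
  appearance head correctly failed. Attribute codings therefore use only
  latents that survive both body-scale normalization and pace changes.
* **Pelvis centering removes common-mode motion.** Vertical pelvis bob
  shifts all joints equally and is annihilated by centering; cues must
  live in relative geometry (proportions, amplitudes, asymmetries).

Strongly coded attributes (sigmoids of one standardized latent each):
Female ← head/torso proportion, AgeChild ← on-screen arm-swing exposure,
AgeAdult ← on-screen stride exposure, BodyFat/BodyThin ← leg/torso ratio,
Side ← viewpoint side exposure. Moderately coded: AgeOver60 ← foot
clearance, Front/Back ← lean direction — real but small-amplitude cues,
comparable to the augmentation noise floor, intentionally hard the way
some attribute groups are hard in real footage. BodyNormal is a
non-monotone bump on the leg ratio. All remaining attributes are
0.5 + weak per-identity noise (clothing/carry/action cannot seriously be
read off a stick figure, and the map does not pretend otherwise). The
monotone codings are property-tested pairwise over 1000 walkers, and a
ridge regression from true latents recovers the coded attributes with
mean R² > 0.9 (map sanity, as distinct from what the network learns).

## Desk-scale studies

Two reference experiments (in `gaitformer.experiments`) exercise the full
pipeline at sizes chosen to run in minutes on one CPU core while leaving
the qualitative effects unambiguous; they are stand-ins for corpus-scale
pretraining, not reproductions of it.

* **Identity recovery** — 50 walkers, 240 frames each; a 2-layer, 64-d
  encoder is pretrained contrastively (80 Adam steps, all identities per
  batch) on the first 192 frames only; rank-1 is measured with probes
  drawn from the unseen 48-frame tail against a training-region gallery.
  Chance is 2%; measured accuracy is consistently ≥ 90% across seeds.
* **Multi-task benefit** — 160 walkers (120 train / 40 held out, 120
  frames each); multitask pretraining (400 steps, ending on a full LR
  cycle — stopping mid-cycle right after the peak learning rate measurably
  degrades the head) is compared with contrastive-only pretraining. The
  appearance head's per-attribute R² on held-out walkers averages well
  above 0.5 on the strongly coded set; the contrastive-only head, which
  receives no gradient, stays at or below zero R².

What these studies show: the implementation learns, the multi-task signal
reaches the appearance head, and identity structure in the embedding
transfers across time within a tracklet. What they do not show: anything
about real pose-tracker noise statistics, real inter-person variability,
cross-camera generalization, or benchmark-scale accuracy — the simulator
has none of that structure.

## Numerical and degenerate-input policy

Normalization guards denominators at 1e-6 and flags rather than drops
degenerate frames; the contrastive loss uses unconditional max-subtraction
and pre-masked self-similarities; BCE clamps at 1e-7; embeddings are
l2-normalized with a 1e-12 floor; resampling at the source FPS is exactly
the identity; crop intervals are half-open with 0-based frame indexing;
ties in nearest-neighbour search resolve to the first gallery index. All
randomness flows from explicit integer seeds through
`numpy.random.Generator`; replaying any training or simulation with the
same seed reproduces losses and weights bit-for-bit (single-threaded
BLAS).

## Known limitations

The NN core is CPU/numpy: fine at desk scale, not a route to 400-epoch
pretraining on 217K tracklets. The appearance head is linear on the pooled
embedding; subtle cues that a post-hoc probe can find in the embedding are
not always extracted by joint training at small step budgets (this is why
the moderately coded attributes are classified as such). The simulator's
viewpoint model scales amplitudes but does not occlude joints, and its
confidence model is independent of pose — real tracker failure modes are
richer.
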