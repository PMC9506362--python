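"""Objectives and optimization loops for contrastive / multi-task pretraining.

The pretraining signal is a supervised contrastive loss over a two-viewed
batch: every tracklet contributes two independent augmentations, the class
label is the tracklet identity, and for anchor i with positives P(i) and
candidates A(i) = batch \\ {i}

    L = mean_i -(1/|P(i)|) sum_{p in P(i)} log
            exp(z_i . z_p / tau) / sum_{a in A(i)} exp(z_i . z_a / tau)

on l2-normalized 128-d projections with temperature tau = 0.001. At that
temperature the logits span thousands, so the log-sum-exp is computed with
unconditional max-subtraction.

In the multi-task regime a soft-label binary cross-entropy on the 42
attribute predictions (both views, same tracklet-level targets) is added
with weight lambda = 0.5:  L_final = L_supcon + lambda * L_appearance.

Pretraining uses Adam under a triangular cyclical learning rate
(1e-4 -> 1e-3 -> 1e-4 per 20-epoch cycle); fine-tuning uses layer-wise
learning-rate decay (geometrically smaller rates toward the input) under a
linear 1e-4 -> 0 schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .augmentation import AugmentConfig, two_views
from .dataset_pipeline import GaitDataset
from .gaitformer_model import GaitFormer, ModelConfig, ModelOutputs, build
from .skeleton_core import TOKEN_DIM

BCE_CLAMP = 1e-7


@dataclass
class TrainingConfig:
    tau: float = 0.001
    lambda_app: float = 0.5
    batch_size: int = 1024          # view-samples: 512 tracklets x 2 views
    epochs: int = 400
    lr_lo: float = 1e-4
    lr_hi: float = 1e-3
    lr_cycle_epochs: int = 20
    finetune_epochs: int = 200
    finetune_lr0: float = 1e-4
    llrd_decay: float = 0.9
    steps_per_epoch: int | None = None   # default: enough to cover the corpus
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.lambda_app < 0:
            raise ValueError("lambda_app must be non-negative")
        if not self.lr_lo < self.lr_hi:
            raise ValueError("lr_lo must be below lr_hi")


# -------------------------------------------------------------------- losses

def _as_tensor(x) -> nn.Tensor:
    return x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, dtype=float))


def l2_normalize(z: nn.Tensor, eps: float = 1e-12) -> nn.Tensor:
    norm = ((z * z).sum(axis=-1, keepdims=True) + eps).sqrt()
    return z / norm


def supcon_loss(projections, labels, tau: float = 0.001):
    """Supervised contrastive loss over a multi-viewed batch.

    Accepts a (2N, d) array or Tensor of projections (l2-normalized
    internally) and per-sample class labels; every sample must have at
    least one positive. Returns a scalar Tensor when the input is a Tensor
    (training path), otherwise a float.
    """
    is_tensor = isinstance(projections, nn.Tensor)
    if not is_tensor:
        # evaluation path: full double precision regardless of the
        # training dtype
        prev = nn.get_default_dtype()
        nn.set_default_dtype(np.float64)
        try:
            return float(supcon_loss(nn.Tensor(np.asarray(projections, float)),
                                     labels, tau).data)
        finally:
            nn.set_default_dtype(prev)
    z = l2_normalize(_as_tensor(projections))
    labels = np.asarray(labels)
    n = z.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    pos_mask = (labels[:, None] == labels[None, :]).astype(float)
    np.fill_diagonal(pos_mask, 0.0)
    pos_counts = pos_mask.sum(axis=1)
    if np.any(pos_counts == 0):
        raise ValueError("every sample needs at least one positive (two-view sampler contract)")
    self_mask = 1.0 - np.eye(n)

    sim = (z @ z.transpose(1, 0)) * (1.0 / tau)
    # stable log-sum-exp over A(i): subtract the per-row max over non-self entries
    diag_neg_inf = np.where(self_mask == 0.0, -np.inf, 0.0)
    row_max = nn.Tensor((sim.data + diag_neg_inf).max(axis=1, keepdims=True))
    shifted = sim - row_max
    # exclude self-similarity from the denominator before exponentiating:
    # its shifted logit is large and positive and would overflow
    exp_masked = (shifted + nn.Tensor(diag_neg_inf)).exp()
    log_denom = exp_masked.sum(axis=1, keepdims=True).log()
    log_prob = shifted - log_denom
    per_anchor = (nn.Tensor(pos_mask) * log_prob).sum(axis=1) * nn.Tensor(1.0 / pos_counts)
    return -(per_anchor.mean())


def soft_bce(pred, target):
    """Soft-label binary cross-entropy, averaged over labels (and batch).

    Predictions are clamped to [1e-7, 1 - 1e-7]; targets may be any soft
    value in [0, 1].
    """
    is_tensor = isinstance(pred, nn.Tensor)
    p = _as_tensor(pred).clip(BCE_CLAMP, 1.0 - BCE_CLAMP)
    y = nn.Tensor(np.asarray(target.data if isinstance(target, nn.Tensor) else target,
                             dtype=float))
    loss = -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()
    return loss if is_tensor else float(loss.data)


def combined_loss(l_supcon, l_appearance, lambda_app: float = 0.5):
    """L_final = L_supcon + lambda * L_appearance."""
    return l_supcon + lambda_app * l_appearance


# ----------------------------------------------------------------- schedules

def cyclical_lr(epoch: float, cfg: TrainingConfig) -> float:
    """Triangular wave: lr_lo at cycle start/end, lr_hi at mid-cycle."""
    cycle = cfg.lr_cycle_epochs
    pos = epoch % cycle
    half = cycle / 2.0
    frac = pos / half if pos <= half else (cycle - pos) / half
    return cfg.lr_lo + (cfg.lr_hi - cfg.lr_lo) * frac


def linear_finetune_lr(epoch: float, cfg: TrainingConfig) -> float:
    """Linear decay from finetune_lr0 to zero across finetune_epochs."""
    frac = min(max(epoch / cfg.finetune_epochs, 0.0), 1.0)
    return cfg.finetune_lr0 * (1.0 - frac)


def llrd_param_groups(model: GaitFormer, lr0: float,
                      decay: float = 0.9) -> list[dict]:
    """Layer-wise LR decay groups: heads at lr0, encoder layer j (counting
    from the top) at lr0 * decay^(j+1), input projection and positional
    table at the smallest rate."""
    heads = (list(model.embedding_head.parameters())
             + list(model.projection_head.parameters())
             + list(model.appearance_head.parameters()))
    groups = [{"params": heads, "lr": lr0}]
    n = len(model.layers)
    for depth_from_top, layer in enumerate(reversed(model.layers)):
        groups.append({"params": list(layer.parameters()),
                       "lr": lr0 * decay ** (depth_from_top + 1)})
    bottom = list(model.input_proj.parameters()) + [model.pos_table]
    groups.append({"params": bottom, "lr": lr0 * decay ** (n + 1)})
    return groups


# -------------------------------------------------------------------- loops

@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    supcon: list[float] = field(default_factory=list)
    appearance: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def as_rows(self) -> list[dict]:
        return [{"epoch": e, "supcon": s, "appearance": a, "total": t, "lr": lr}
                for e, s, a, t, lr in zip(self.epochs, self.supcon,
                                          self.appearance, self.total, self.lr)]


def make_view_batch(dataset: GaitDataset, indices: np.ndarray,
                    aug: AugmentConfig, rng: np.random.Generator):
    """Two-view batch: tokens (2N, T, 54) and labels where each tracklet
    index appears exactly twice (views are interleaved)."""
    tokens = np.empty((2 * len(indices), aug.crop_T, TOKEN_DIM))
    labels = np.empty(2 * len(indices), dtype=int)
    for k, idx in enumerate(indices):
        va, vb = two_views(dataset.sequences[idx].data, aug, rng)
        tokens[2 * k] = va.reshape(aug.crop_T, TOKEN_DIM)
        tokens[2 * k + 1] = vb.reshape(aug.crop_T, TOKEN_DIM)
        labels[2 * k] = labels[2 * k + 1] = idx
    return tokens, labels


def pretrain(dataset: GaitDataset, model_cfg: ModelConfig,
             train_cfg: TrainingConfig, mode: str = "contrastive",
             model: GaitFormer | None = None):
    """Contrastive or multi-task pretraining over a filtered corpus.

    Each step samples tracklets, builds a two-view batch, evaluates the
    supervised contrastive loss on the 128-d projections (plus the
    lambda-weighted attribute BCE on both views in multi-task mode) and
    takes an Adam step under the cyclical schedule. Returns (model,
    history); fully reproducible from ``train_cfg.seed``.
    """
    if mode not in ("contrastive", "multitask"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if mode == "multitask" and dataset.attributes is None:
        raise ValueError("multitask pretraining needs attribute labels")

    rng = np.random.default_rng(train_cfg.seed)
    if model is None:
        model = build(model_cfg, seed=int(rng.integers(0, 2 ** 31 - 1)))
    optim = nn.Adam(model.parameters(), lr=train_cfg.lr_lo)
    n_tracklets_per_batch = min(max(train_cfg.batch_size // 2, 2), len(dataset))
    steps = train_cfg.steps_per_epoch or max(1, len(dataset) // n_tracklets_per_batch)
    history = TrainingHistory()

    for epoch in range(train_cfg.epochs):
        lr = cyclical_lr(epoch, train_cfg)
        optim.set_lr(lr)
        sup_sum = app_sum = 0.0
        for _ in range(steps):
            indices = rng.choice(len(dataset), size=n_tracklets_per_batch, replace=False)
            tokens, labels = make_view_batch(dataset, indices, train_cfg.augment, rng)
            out: ModelOutputs = model.forward(nn.Tensor(tokens))
            l_sup = supcon_loss(out.projection, labels, train_cfg.tau)
            if mode == "multitask":
                targets = dataset.attributes[labels]   # same labels for both views
                l_app = soft_bce(out.attributes, targets)
                loss = combined_loss(l_sup, l_app, train_cfg.lambda_app)
                app_sum += float(l_app.data)
            else:
                loss = l_sup
            optim.zero_grad()
            loss.backward()
            optim.step()
            sup_sum += float(l_sup.data)
        history.epochs.append(epoch)
        history.supcon.append(sup_sum / steps)
        history.appearance.append(app_sum / steps if mode == "multitask" else float("nan"))
        history.total.append((sup_sum + train_cfg.lambda_app * app_sum) / steps
                             if mode == "multitask" else sup_sum / steps)
        history.lr.append(lr)
    return model, history


def finetune(model: GaitFormer, sequences: list, labels, task: str,
             train_cfg: TrainingConfig, epochs: int | None = None):
    """Task fine-tuning with LLRD parameter groups and a linear LR decay.

    ``recognition`` trains the contrastive loss with the subject ID as the
    class; ``gender`` trains a fresh scalar sigmoid head with BCE. Sequences
    are expected pre-cropped to the training length. Returns (model, extras)
    where extras holds the gender head when applicable.
    """
    if task not in ("recognition", "gender"):
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng(train_cfg.seed)
    labels = np.asarray(labels)
    tokens_all = np.stack([s.data.reshape(len(s), TOKEN_DIM) for s in sequences])
    n = len(sequences)
    epochs = epochs if epochs is not None else train_cfg.finetune_epochs

    groups = llrd_param_groups(model, train_cfg.finetune_lr0, train_cfg.llrd_decay)
    gender_head = None
    if task == "gender":
        gender_head = nn.Linear(model.config.emb_dim, 1, rng)
        groups[0]["params"] = groups[0]["params"] + list(gender_head.parameters())
    optim = nn.Adam(groups)

    batch = min(n, 64)
    for epoch in range(epochs):
        optim.set_lr(linear_finetune_lr(epoch, train_cfg), scale_groups=True)
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            if task == "recognition" and len(np.unique(labels[idx])) == len(idx):
                continue    # no positive pair in this batch
            out = model.forward(nn.Tensor(tokens_all[idx]))
            if task == "recognition":
                loss = supcon_loss(out.projection, labels[idx], train_cfg.tau)
            else:
                logit = gender_head(out.embedding)
                pred = logit.sigmoid().reshape(len(idx))
                loss = soft_bce(pred, labels[idx].astype(float))
            optim.zero_grad()
            loss.backward()
            optim.step()
    return model, {"gender_head": gender_head}
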