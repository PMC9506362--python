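"""Desk-scale study protocols on synthetic walker corpora.

These are the package's reference experiments, shared by the test suite
and the results-reproduction script:

* identity recovery — contrastive pretraining of a tiny encoder on one
  tracklet per identity, then rank-1 recognition where the probe is a
  temporal segment never seen during training (the direct-transfer
  protocol at desk scale, against a 1/n_ids chance level);
* multi-task benefit — multitask vs contrastive-only pretraining, scored
  by appearance-head R² against the generator's attribute labels on
  held-out walkers.

Problem sizes (identities, frames, steps) are chosen so a trial runs in
minutes on one CPU core while leaving the qualitative effects clearly
measurable; docs/methods.md discusses the choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .attribute_annotation import load_schema
from .augmentation import AugmentConfig
from .dataset_pipeline import GaitDataset, build_dataset
from .evaluation import attribute_r2, extract_embeddings, rank1
from .gaitformer_model import ModelConfig
from .skeleton_core import NormalizedSequence, TOKEN_DIM, center_crop
from .synthetic_data import CODED, STRONGLY_CODED, make_pretraining_corpus
from .training import TrainingConfig, pretrain


def tiny_model_config() -> ModelConfig:
    """2-layer, 64-d encoder: the desk-scale stand-in for the SM model."""
    return ModelConfig(n_layers=2, d_model=64, n_heads=4, ff_dim=128,
                       emb_dim=64, proj_dim=32)


def _truncate(seq: NormalizedSequence, stop: int) -> NormalizedSequence:
    return NormalizedSequence(seq.data[:stop], seq.ref_fps, seq.track_id)


def _tail(seq: NormalizedSequence, start: int) -> NormalizedSequence:
    return NormalizedSequence(seq.data[start:], seq.ref_fps, seq.track_id)


@dataclass
class IdentityRecoveryResult:
    rank1_percent: float
    chance_percent: float
    n_ids: int
    final_supcon: float


def identity_recovery_trial(seed: int, n_ids: int = 50, frames_per_id: int = 240,
                            train_frames: int = 192, epochs: int = 40,
                            steps_per_epoch: int = 2) -> IdentityRecoveryResult:
    """Contrastive pretraining, then rank-1 on held-out temporal crops.

    Training only ever sees the first ``train_frames`` frames of each
    tracklet; the probe embedding comes from the remaining tail, the
    gallery from the training region, so a correct match requires an
    identity representation that transfers across time.
    """
    corpus = make_pretraining_corpus(n_ids, frames_per_id, seed=seed)
    ds = build_dataset(corpus.tracklets)
    train = GaitDataset([_truncate(s, train_frames) for s in ds.sequences], ds.ids)
    cfg = TrainingConfig(batch_size=2 * len(train), epochs=epochs,
                         steps_per_epoch=steps_per_epoch, seed=seed,
                         augment=AugmentConfig())
    model, history = pretrain(train, tiny_model_config(), cfg, mode="contrastive")

    gallery_seqs = [_truncate(s, train_frames) for s in ds.sequences]
    probe_seqs = [_tail(s, train_frames) for s in ds.sequences]
    gallery = extract_embeddings(model, gallery_seqs)
    probe = extract_embeddings(model, probe_seqs)
    ids = np.arange(len(ds))
    return IdentityRecoveryResult(
        rank1_percent=rank1(gallery, ids, probe, ids),
        chance_percent=100.0 / len(ds),
        n_ids=len(ds),
        final_supcon=history.supcon[-1])


@dataclass
class MultiTaskBenefitResult:
    strong_r2_multitask: float
    coded_r2_multitask: float
    strong_r2_contrastive: float
    coded_r2_contrastive: float
    per_attribute_multitask: dict[str, float]


def _head_r2(model, sequences, targets):
    tokens = np.stack([center_crop(s, 48).data.reshape(48, TOKEN_DIM)
                       for s in sequences])
    with nn.no_grad():
        preds = model.forward(nn.Tensor(tokens)).attributes.data.astype(float)
    r2 = attribute_r2(preds, targets)
    return r2


def multitask_benefit_trial(seed: int, n_ids: int = 200, n_train: int = 140,
                            frames_per_id: int = 120, epochs: int = 400,
                            contrastive_epochs: int = 60,
                            steps_per_epoch: int = 2) -> MultiTaskBenefitResult:
    """Attribute distillation: multitask vs contrastive-only pretraining.

    The appearance head is scored by per-attribute R² against the
    generator's soft labels on walkers never seen in training. The
    contrastive-only run leaves the appearance head untrained, so its R²
    measures the chance level of an uninformed head.
    """
    schema = load_schema()
    corpus = make_pretraining_corpus(n_ids, frames_per_id, seed=seed)
    ds = build_dataset(corpus.tracklets)
    ds.attributes = corpus.attributes
    train = GaitDataset(ds.sequences[:n_train], ds.ids[:n_train],
                        attributes=ds.attributes[:n_train])
    test_seqs = ds.sequences[n_train:]
    test_attrs = ds.attributes[n_train:]
    idx_strong = [schema.index(a) for a in STRONGLY_CODED]
    idx_coded = [schema.index(a) for a in CODED]
    model_cfg = tiny_model_config()

    mt_cfg = TrainingConfig(batch_size=100, epochs=epochs,
                            steps_per_epoch=steps_per_epoch, seed=seed)
    mt_model, _ = pretrain(train, model_cfg, mt_cfg, mode="multitask")
    r2_mt = _head_r2(mt_model, test_seqs, test_attrs)

    co_cfg = TrainingConfig(batch_size=100, epochs=contrastive_epochs,
                            steps_per_epoch=steps_per_epoch, seed=seed)
    co_model, _ = pretrain(train, model_cfg, co_cfg, mode="contrastive")
    r2_co = _head_r2(co_model, test_seqs, test_attrs)

    return MultiTaskBenefitResult(
        strong_r2_multitask=float(np.nanmean(r2_mt[idx_strong])),
        coded_r2_multitask=float(np.nanmean(r2_mt[idx_coded])),
        strong_r2_contrastive=float(np.nanmean(r2_co[idx_strong])),
        coded_r2_contrastive=float(np.nanmean(r2_co[idx_coded])),
        per_attribute_multitask={a: float(r2_mt[schema.index(a)])
                                 for a in CODED})
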