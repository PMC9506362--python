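"""Evaluation protocols: direct-transfer embeddings, rank-1 recognition
(including the cross-view gallery/probe protocol), gender metrics and
per-attribute R².

Direct transfer takes a deterministic center crop of T = 48 frames, runs
the encoder once (no test-time augmentation) and l2-normalizes the 256-d
embedding. Recognition is rank-1 nearest neighbour under cosine
similarity (equivalently Euclidean ranking on the unit sphere); in the
cross-view protocol each viewpoint in turn is the probe set while the
gallery holds every other viewpoint. Attribute quality is the per-attribute
coefficient of determination R² against the soft pseudo-labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .gaitformer_model import GaitFormer
from .skeleton_core import NormalizedSequence, TOKEN_DIM, center_crop


@dataclass
class EvalReport:
    rank1: float | None = None
    per_view_rank1: dict = field(default_factory=dict)
    mean_cross_view_rank1: float | None = None
    gender_precision: float | None = None
    gender_recall: float | None = None
    gender_f1: float | None = None
    attribute_r2: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


def extract_embeddings(model: GaitFormer, sequences: list[NormalizedSequence],
                       T: int = 48, batch_size: int = 256) -> np.ndarray:
    """Center-crop, encode and l2-normalize; rows are unit 256-d vectors."""
    for s in sequences:
        if len(s) < T:
            raise ValueError(f"sequence of length {len(s)} shorter than T={T}")
    tokens = np.stack([center_crop(s, T).data.reshape(T, TOKEN_DIM)
                       for s in sequences])
    outs = []
    with nn.no_grad():
        for start in range(0, len(tokens), batch_size):
            out = model.forward(nn.Tensor(tokens[start:start + batch_size]))
            outs.append(out.embedding.data.astype(float))
    emb = np.concatenate(outs, axis=0)
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    return emb / np.maximum(norms, 1e-12)


def rank1(gallery_emb: np.ndarray, gallery_ids, probe_emb: np.ndarray,
          probe_ids) -> float:
    """Rank-1 accuracy in percent: fraction of probes whose nearest gallery
    embedding (cosine; ties -> first gallery index) shares their subject."""
    gallery_emb = np.asarray(gallery_emb, dtype=float)
    probe_emb = np.asarray(probe_emb, dtype=float)
    if gallery_emb.size == 0:
        raise ValueError("empty gallery")
    gallery_ids = np.asarray(gallery_ids)
    probe_ids = np.asarray(probe_ids)
    sims = probe_emb @ gallery_emb.T
    best = sims.argmax(axis=1)          # argmax takes the first maximal index
    return float((gallery_ids[best] == probe_ids).mean() * 100.0)


def cross_view_rank1(embeddings: np.ndarray, subjects, views) -> tuple[dict, float, dict]:
    """Per-view rank-1 where the gallery is every *other* viewpoint.

    Probes whose subject never appears in their cross-view gallery are
    skipped with a warning and counted in the coverage statistic. Returns
    (per-view accuracies, mean over views, coverage info).
    """
    subjects = np.asarray(subjects)
    views = np.asarray(views)
    uniq_views = np.unique(views)
    if len(uniq_views) < 2:
        raise ValueError("cross-view protocol needs at least two viewpoints")
    per_view: dict = {}
    coverage: dict = {}
    for v in uniq_views:
        probe_mask = views == v
        gallery_mask = ~probe_mask
        gal_subjects = set(subjects[gallery_mask].tolist())
        usable = probe_mask & np.isin(subjects, list(gal_subjects))
        skipped = int(probe_mask.sum() - usable.sum())
        if skipped:
            warnings.warn(f"view {v!r}: {skipped} probe(s) without a cross-view "
                          "gallery subject were skipped", stacklevel=2)
        coverage[v] = {"probes": int(probe_mask.sum()), "skipped": skipped}
        if not usable.any():
            continue
        per_view[v] = rank1(embeddings[gallery_mask], subjects[gallery_mask],
                            embeddings[usable], subjects[usable])
    mean_acc = float(np.mean(list(per_view.values()))) if per_view else float("nan")
    return per_view, mean_acc, coverage


def gender_metrics(y_true, y_prob, threshold: float = 0.5) -> tuple[float, float, float]:
    """Macro-averaged precision / recall / F1 (percent) at a 0.5 threshold."""
    from sklearn.metrics import precision_recall_fscore_support

    y_true = np.asarray(y_true).astype(int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present in the ground truth")
    y_pred = (np.asarray(y_prob, dtype=float) >= threshold).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", labels=[0, 1], zero_division=0)
    return float(p * 100), float(r * 100), float(f1 * 100)


def attribute_r2(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Per-attribute R² = 1 - SS_res/SS_tot against the soft labels.

    Attributes whose target variance is zero are undefined and reported as
    NaN, never as 0.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape or pred.ndim != 2:
        raise ValueError("pred and target must be matching (N, K) matrices")
    if pred.shape[0] < 2:
        raise ValueError("R² needs at least two samples")
    ss_res = ((target - pred) ** 2).sum(axis=0)
    ss_tot = ((target - target.mean(axis=0)) ** 2).sum(axis=0)
    out = np.full(pred.shape[1], np.nan)
    ok = ss_tot > 0
    out[ok] = 1.0 - ss_res[ok] / ss_tot[ok]
    return out
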