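"""Soft-label attribute annotation of tracklets via an ensemble of
pedestrian-attribute predictors.

Each tracklet is annotated with 42 appearance attributes in 8 groups
(gender, age group, body type, viewpoint, carry conditions, clothing,
footwear, apparent action). The procedure, per tracklet:

1. sample the pedestrian crop every T frames (T = 48, the period length);
2. predict each crop k = 4 times under random light augmentations
   (horizontal flip, small rotation, brightness/contrast jitter) and
   average, for robustness to imaging noise;
3. coalesce the three source vocabularies (PA100k / PETA / RAP) onto the
   42-target schema (mean or max per target, see the shipped YAML);
4. pool crop-level predictions into one tracklet-level vector, weighting
   each crop by its bounding-box area relative to the image — nearer,
   larger crops are more trustworthy.

Labels stay soft (never rounded): the downstream appearance head is
trained by distillation against these probabilities.

Predictors are an abstract interface: any callable mapping an image crop
to a score vector aligned with one source vocabulary. Tests use
deterministic mocks; no pretrained weights are required anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .skeleton_core import RawTracklet

N_ATTRIBUTES = 42
GROUP_NAMES = ("Gender", "AgeGroup", "BodyType", "Viewpoint",
               "CarryConditions", "Clothing", "Footwear", "ApparentAction")


class SchemaError(ValueError):
    """Raised at load time for an incomplete or inconsistent schema."""


@dataclass(frozen=True)
class SourceRef:
    dataset: str
    label: str
    invert: bool = False


@dataclass
class AttributeSchema:
    """42 named targets, their groups, and the source-label coalescing map."""

    names: tuple[str, ...]
    groups: dict[str, str]                      # target -> group
    source_labels: dict[str, tuple[str, ...]]   # dataset -> ordered labels
    coalesce_map: dict[str, tuple[str, list[SourceRef]]]  # target -> (mode, refs)
    dropped: frozenset[tuple[str, str]]
    version: int = 1

    def index(self, name: str) -> int:
        return self.names.index(name)

    def group_members(self, group: str) -> list[str]:
        return [n for n in self.names if self.groups[n] == group]


def load_schema(path=None) -> AttributeSchema:
    """Load and validate a schema file (default: the shipped YAML).

    Validation is strict: exactly 42 targets, exactly 8 non-empty groups,
    and every source label either mapped to a target or explicitly dropped
    — an unreferenced label is a configuration error here, not a silent
    runtime surprise.
    """
    if path is None:
        text = (resources.files("gaitformer") / "data" / "attribute_schema.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)

    groups_spec: dict[str, list[str]] = raw["groups"]
    names = tuple(n for g in groups_spec.values() for n in g)
    if len(names) != N_ATTRIBUTES:
        raise SchemaError(f"schema must define {N_ATTRIBUTES} targets, got {len(names)}")
    if len(set(names)) != len(names):
        raise SchemaError("duplicate target names")
    if set(groups_spec) != set(GROUP_NAMES) or any(not g for g in groups_spec.values()):
        raise SchemaError("schema must define exactly the 8 canonical non-empty groups")
    groups = {n: g for g, members in groups_spec.items() for n in members}

    source_labels = {ds: tuple(labels) for ds, labels in raw["sources"].items()}
    coalesce_map: dict[str, tuple[str, list[SourceRef]]] = {}
    referenced: set[tuple[str, str]] = set()
    for target, entry in raw["coalesce"].items():
        if target not in groups:
            raise SchemaError(f"coalesce target {target!r} is not a schema target")
        mode = entry.get("mode", "average")
        if mode not in ("average", "max"):
            raise SchemaError(f"unknown mode {mode!r} for {target!r}")
        refs = [SourceRef(s["dataset"], s["label"], bool(s.get("invert", False)))
                for s in entry["sources"]]
        for ref in refs:
            if ref.label not in source_labels.get(ref.dataset, ()):
                raise SchemaError(f"{ref.dataset}/{ref.label} is not a known source label")
            referenced.add((ref.dataset, ref.label))
        coalesce_map[target] = (mode, refs)
    missing_targets = set(names) - set(coalesce_map)
    if missing_targets:
        raise SchemaError(f"targets without sources: {sorted(missing_targets)}")

    dropped = frozenset((d["dataset"], d["label"]) for d in raw.get("drop", []))
    all_labels = {(ds, lab) for ds, labels in source_labels.items() for lab in labels}
    unmapped = all_labels - referenced - dropped
    if unmapped:
        raise SchemaError(f"source labels neither mapped nor dropped: {sorted(unmapped)}")

    return AttributeSchema(names=names, groups=groups, source_labels=source_labels,
                           coalesce_map=coalesce_map, dropped=dropped,
                           version=int(raw.get("version", 1)))


@dataclass
class AttributeVector:
    """42 soft labels in [0, 1]; indexing follows the schema order."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_ATTRIBUTES,):
            raise ValueError(f"expected {N_ATTRIBUTES} values, got {self.values.shape}")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("soft labels must lie in [0, 1]")


@dataclass
class AugmentDescriptor:
    """Abstract image-augmentation parameters for one predictor call."""

    flip: bool = False
    angle_deg: float = 0.0
    brightness: float = 0.0    # additive, fraction of full range
    contrast: float = 1.0      # multiplicative


@dataclass
class AnnotationConfig:
    k_augment: int = 4
    period_T: int = 48
    flip_p: float = 0.5
    max_angle_deg: float = 10.0
    max_brightness: float = 0.1
    contrast_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self):
        if self.k_augment < 1:
            raise ValueError("k_augment must be >= 1")


def sample_augment(rng: np.random.Generator, cfg: AnnotationConfig) -> AugmentDescriptor:
    return AugmentDescriptor(
        flip=bool(rng.random() < cfg.flip_p),
        angle_deg=float(rng.uniform(-cfg.max_angle_deg, cfg.max_angle_deg)),
        brightness=float(rng.uniform(-cfg.max_brightness, cfg.max_brightness)),
        contrast=float(rng.uniform(*cfg.contrast_range)),
    )


def apply_augment(crop: np.ndarray, desc: AugmentDescriptor) -> np.ndarray:
    """Apply a descriptor to an image array (H x W [x C], values in [0, 1])."""
    from scipy import ndimage

    out = np.asarray(crop, dtype=float)
    if desc.flip:
        out = out[:, ::-1]
    if desc.angle_deg != 0.0:
        out = ndimage.rotate(out, desc.angle_deg, reshape=False, order=1, mode="nearest")
    out = np.clip(out * desc.contrast + desc.brightness, 0.0, 1.0)
    return out


# ------------------------------------------------------------------ operations

def coalesce(source_preds: dict[str, np.ndarray],
             schema: AttributeSchema) -> AttributeVector:
    """Map source-vocabulary score vectors onto the 42-target schema.

    ``source_preds`` holds, per dataset name, a vector aligned with that
    dataset's label list. Targets average (or max) their mapped scores;
    dropped labels are ignored.
    """
    for ds, vec in source_preds.items():
        expected = len(schema.source_labels[ds])
        if len(vec) != expected:
            raise ValueError(f"{ds} prediction has {len(vec)} labels, expected {expected}")
    out = np.zeros(N_ATTRIBUTES)
    for i, target in enumerate(schema.names):
        mode, refs = schema.coalesce_map[target]
        scores = []
        for ref in refs:
            if ref.dataset not in source_preds:
                continue
            idx = schema.source_labels[ref.dataset].index(ref.label)
            s = float(source_preds[ref.dataset][idx])
            scores.append(1.0 - s if ref.invert else s)
        if not scores:
            raise ValueError(f"no source prediction available for target {target!r}")
        out[i] = max(scores) if mode == "max" else float(np.mean(scores))
    return AttributeVector(np.clip(out, 0.0, 1.0))


def predict_crop(predictor, crop, cfg: AnnotationConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Augmentation-averaged prediction: mean over k augmented copies.

    A predictor failure on one copy skips that copy; if every copy fails
    the error is raised.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    preds = []
    last_err: Exception | None = None
    for _ in range(cfg.k_augment):
        desc = sample_augment(rng, cfg)
        try:
            aug = apply_augment(crop, desc) if isinstance(crop, np.ndarray) else crop
            preds.append(np.asarray(predictor(aug, desc), dtype=float))
        except Exception as err:  # noqa: BLE001 - predictor is third-party code
            last_err = err
    if not preds:
        raise RuntimeError("attribute predictor failed on every augmented copy") from last_err
    return np.mean(preds, axis=0)


def sample_crops(track: RawTracklet, period_T: int = 48) -> list[tuple[int, np.ndarray]]:
    """Pick the pedestrian crop every ``period_T`` frames: positions 0, T, 2T, ..."""
    bboxes = track.bboxes
    if bboxes is None:
        raise ValueError("tracklet has no bounding boxes")
    return [(t, bboxes[t]) for t in range(0, len(track), period_T)]


def relative_areas(track: RawTracklet, positions: list[int]) -> np.ndarray:
    """Bounding-box area relative to the image area (or, when the frame
    size is unknown, to the largest box in the tracklet)."""
    bboxes = track.bboxes
    areas = np.array([bboxes[t][2] * bboxes[t][3] for t in positions], dtype=float)
    if track.frame_size is not None:
        frame_area = track.frame_size[0] * track.frame_size[1]
    else:
        all_areas = bboxes[:, 2] * bboxes[:, 3]
        frame_area = float(all_areas.max())
    if frame_area <= 0:
        raise ValueError("non-positive reference area")
    return areas / frame_area


def aggregate_tracklet(crop_preds: list[AttributeVector],
                       rel_areas) -> AttributeVector:
    """Area-weighted mean of crop-level predictions (larger crop, more weight)."""
    rel_areas = np.asarray(rel_areas, dtype=float)
    if len(crop_preds) != len(rel_areas):
        raise ValueError("predictions and areas must align")
    if np.any(rel_areas < 0):
        raise ValueError("areas must be non-negative")
    total = rel_areas.sum()
    if total <= 0:
        raise ValueError("all-zero crop areas")
    weights = rel_areas / total
    stacked = np.stack([p.values for p in crop_preds])
    return AttributeVector(weights @ stacked)


def annotate_tracklet(track: RawTracklet, predictors: dict[str, object],
                      schema: AttributeSchema, cfg: AnnotationConfig,
                      rng: np.random.Generator | None = None) -> AttributeVector:
    """Full per-tracklet annotation: sample -> predict (k-augment averaged)
    -> coalesce -> area-weighted pooling."""
    rng = rng or np.random.default_rng(cfg.seed)
    samples = sample_crops(track, cfg.period_T)
    positions = [t for t, _ in samples]
    crops = track.crops if track.crops is not None else [None] * len(track)
    per_crop: list[AttributeVector] = []
    for t in positions:
        source_preds = {ds: predict_crop(pred, crops[t], cfg, rng)
                        for ds, pred in predictors.items()}
        per_crop.append(coalesce(source_preds, schema))
    return aggregate_tracklet(per_crop, relative_areas(track, positions))
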