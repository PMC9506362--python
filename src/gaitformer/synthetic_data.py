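"""Synthetic walker simulator: tracker-style fixtures with planted defects
and kinematic corpora with known identity and attribute structure.

The kinematic model is deliberately simple — coupled sinusoids plus noise,
not biomechanics. It reproduces the statistical structure the learning
method assumes: periodic anti-phase leg motion at an identity-specific
cadence, counter-phased arm swing, pelvis bob, per-joint detection
confidences, and a camera viewpoint that forescales horizontal amplitudes.
Each walker's latent parameters map monotonically onto a subset of the 42
appearance attributes, so attribute recoverability is measurable against
ground truth; clothing/carry/action attributes get weak, noise-dominated
signals on purpose (they are hard in real footage too).

Everything is deterministic from a seed: same seed, same corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attribute_annotation import AttributeVector, load_schema
from .dataset_pipeline import PipelineConfig
from .skeleton_core import RawTracklet

# joint indices (COCO-18)
_NOSE, _NECK = 0, 1
_RSH, _RELB, _RWRI = 2, 3, 4
_LSH, _LELB, _LWRI = 5, 6, 7
_RHIP, _RKNEE, _RANK = 8, 9, 10
_LHIP, _LKNEE, _LANK = 11, 12, 13
_REYE, _LEYE, _REAR, _LEAR = 14, 15, 16, 17

FRAME_SIZE = (1920.0, 1080.0)

#: attributes carrying a strong, large-amplitude movement code that survives
#: body-scale normalization and the pace augmentation: head/body proportions,
#: on-screen swing amplitudes, viewpoint exposure
STRONGLY_CODED = ("Female", "AgeChild", "AgeAdult", "BodyFat", "BodyThin", "Side")
#: subtler codings (forward lean direction, foot-clearance amplitude): real
#: signals, but small relative to augmentation noise — deliberately hard,
#: the way some attribute groups are hard in real footage
MODERATELY_CODED = ("AgeOver60", "Front", "Back")
#: all movement-coded attributes (strong + moderate + the non-monotone body bump)
CODED = STRONGLY_CODED + MODERATELY_CODED + ("BodyNormal",)

#: declared monotone codings: attribute -> (latent, sign); the latent is a
#: WalkerParams field or one of the derived view latents below. Codings use
#: only latents that survive both body-scale normalization and the
#: training-time pace augmentation (which deliberately randomizes cadence),
#: so each coded attribute is in principle recoverable from the model input.
MONOTONE_CODING = {
    "Female": ("head_ratio", +1),
    "AgeChild": ("arm_exposure", +1),
    "AgeAdult": ("stride_exposure", +1),
    "AgeOver60": ("lift_ratio", -1),
    "BodyFat": ("leg_ratio", -1),
    "BodyThin": ("leg_ratio", +1),
    "Front": ("cos_view", +1),
    "Back": ("cos_view", -1),
    "Side": ("side_exposure", +1),
}


@dataclass(frozen=True)
class WalkerParams:
    """Latent kinematic identity of one synthetic walker."""

    gait_frequency: float      # Hz, ~0.7-1.2
    stride_ratio: float        # leg swing amplitude / shoulder width
    arm_ratio: float           # arm swing amplitude / shoulder width
    torso_height: float        # px, pelvis -> neck
    shoulder_ratio: float      # shoulder width / torso height
    leg_ratio: float           # leg length / torso height
    head_ratio: float          # nose height above pelvis / torso height
    bob_ratio: float           # vertical pelvis-bob amplitude / torso height
    lift_ratio: float          # ankle foot-clearance amplitude / torso height
    view_angle: float          # rad in [pi/6, 5pi/6]; pi/2 = pure side view
    phase: float               # gait phase offset
    noise_px: float            # per-joint coordinate noise, px
    seed: int

    @property
    def cos_view(self) -> float:
        return float(np.cos(self.view_angle))

    @property
    def side_exposure(self) -> float:
        return float(abs(np.sin(self.view_angle)))

    # Observable (post-normalization) swing amplitudes: what an annotator —
    # or the encoder — actually sees on screen. Horizontal amplitudes are
    # foreshortened by the view while the normalizing shoulder span is
    # foreshortened at a different rate.
    @property
    def stride_exposure(self) -> float:
        return self.stride_ratio * self.side_exposure / (0.75 + 0.25 * abs(self.cos_view))

    @property
    def arm_exposure(self) -> float:
        return self.arm_ratio * self.side_exposure / (0.75 + 0.25 * abs(self.cos_view))

    def latent(self, name: str) -> float:
        return getattr(self, name)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def attribute_map(params: WalkerParams) -> AttributeVector:
    """Fixed deterministic map from walker latents to 42 soft labels.

    Strongly coded attributes are sigmoids of a single standardized latent
    (see MONOTONE_CODING); the remaining attributes are 0.5 plus weak
    per-identity noise.
    """
    schema = _schema()
    zf = (params.gait_frequency - 0.95) / 0.13
    zs = (params.stride_exposure - 0.17) / 0.07
    za = (params.arm_exposure - 0.19) / 0.08
    zl = (params.leg_ratio - 1.00) / 0.09
    zh = (params.head_ratio - 1.15) / 0.055
    zi = (params.lift_ratio - 0.045) / 0.017
    c = params.cos_view
    s = params.side_exposure

    strong = {
        "Female": _sigmoid(1.5 * zh),
        "AgeChild": _sigmoid(1.5 * za),
        "AgeAdult": _sigmoid(1.5 * zs),
        "AgeOver60": _sigmoid(-1.5 * zi),
        "BodyFat": _sigmoid(-1.5 * zl),
        "BodyThin": _sigmoid(1.5 * zl),
        "Front": _sigmoid(2.5 * (c - 0.2)),
        "Back": _sigmoid(2.5 * (-c - 0.2)),
        "Side": _sigmoid(6.0 * (s - 0.8)),
        "BodyNormal": 0.15 + 0.8 * float(np.exp(-0.5 * zl ** 2)),
    }
    rng = np.random.default_rng(params.seed + 104729)   # label-noise stream
    values = np.empty(len(schema.names))
    mix = 0.2 * zf - 0.15 * zs + 0.1 * zl
    for i, name in enumerate(schema.names):
        if name in strong:
            values[i] = strong[name]
        else:
            values[i] = 0.5 + 0.12 * np.tanh(rng.normal(0.0, 1.0)) + 0.03 * np.tanh(mix)
    return AttributeVector(np.clip(values, 0.005, 0.995))


_SCHEMA_CACHE = None


def _schema():
    global _SCHEMA_CACHE
    if _SCHEMA_CACHE is None:
        _SCHEMA_CACHE = load_schema()
    return _SCHEMA_CACHE


def sample_walker(seed: int) -> tuple[WalkerParams, AttributeVector]:
    """Draw one identity's parameters (deterministic in ``seed``)."""
    rng = np.random.default_rng(seed)
    params = WalkerParams(
        gait_frequency=float(rng.uniform(0.7, 1.2)),
        stride_ratio=float(rng.uniform(0.12, 0.26)),
        arm_ratio=float(rng.uniform(0.10, 0.30)),
        torso_height=float(rng.uniform(50.0, 90.0)),
        shoulder_ratio=float(rng.uniform(0.38, 0.55)),
        leg_ratio=float(rng.uniform(0.85, 1.15)),
        head_ratio=float(rng.uniform(1.05, 1.25)),
        bob_ratio=float(rng.uniform(0.02, 0.06)),
        lift_ratio=float(rng.uniform(0.015, 0.075)),
        view_angle=float(rng.uniform(np.pi / 6, 5 * np.pi / 6)),
        phase=float(rng.uniform(0.0, 2 * np.pi)),
        noise_px=float(rng.uniform(0.05, 0.3)),
        seed=int(seed),
    )
    return params, attribute_map(params)


def render_tracklet(params: WalkerParams, n_frames: int, fps: float = 24.0,
                    rng: np.random.Generator | None = None,
                    track_id: str | None = None,
                    conf_beta: tuple[float, float] = (18.0, 2.0),
                    defect: str | None = None) -> RawTracklet:
    """Render a walker into tracker-style output (coords, confs, boxes).

    ``defect`` plants exactly one pipeline violation: ``static`` (no limb
    motion), ``erratic`` (leg tracking glitches), ``low_conf`` /
    ``low_feet_conf`` (confidence collapse). Nominal renders are calibrated
    to pass every construction filter.
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    rng = rng or np.random.default_rng(params.seed)
    h = params.torso_height
    w = params.shoulder_ratio * h
    leg = params.leg_ratio * h
    c = params.cos_view
    s_body = 0.75 + 0.25 * abs(c)       # shoulder foreshortening
    s_hip = 0.30 + 0.70 * abs(c)        # hips forescale faster than shoulders
    s_mot = params.side_exposure        # horizontal motion foreshortening
    A_leg = params.stride_ratio * w
    A_arm = params.arm_ratio * w
    if defect == "static":
        A_leg = A_arm = 0.0

    t = np.arange(n_frames) / fps
    phi = 2 * np.pi * params.gait_frequency * t + params.phase
    lean = 0.25 * w * c                  # forward lean encodes facing direction

    coords = np.zeros((n_frames, 18, 2))
    hw = 0.30 * w * s_hip

    def put(j, x, y):
        coords[:, j, 0] = x
        coords[:, j, 1] = y

    bob = (params.bob_ratio * h * np.sin(2 * phi)
           if defect != "static" else np.zeros(n_frames))
    leg_swing = A_leg * np.sin(phi) * s_mot          # right leg
    arm_swing = A_arm * np.sin(phi + np.pi) * s_mot  # right arm counter-phased
    lift_amp = params.lift_ratio * h if defect != "static" else 0.0
    lift_r = lift_amp * np.abs(np.cos(phi))
    lift_l = lift_amp * np.abs(np.cos(phi + np.pi))

    hr = params.head_ratio
    put(_NECK, lean * 1.0, -h)
    put(_NOSE, lean * 1.15, -hr * h)
    put(_REYE, lean * 1.2 - 0.06 * w * s_body, -(hr + 0.05) * h)
    put(_LEYE, lean * 1.2 + 0.06 * w * s_body, -(hr + 0.05) * h)
    put(_REAR, lean * 1.15 - 0.09 * w * s_body, -(hr + 0.01) * h)
    put(_LEAR, lean * 1.15 + 0.09 * w * s_body, -(hr + 0.01) * h)
    put(_RSH, lean - 0.5 * w * s_body, -h)
    put(_LSH, lean + 0.5 * w * s_body, -h)
    put(_RELB, lean - 0.5 * w * s_body + 0.5 * arm_swing, -0.5 * h)
    put(_LELB, lean + 0.5 * w * s_body - 0.5 * arm_swing, -0.5 * h)
    put(_RWRI, lean - 0.5 * w * s_body + arm_swing, -0.05 * h)
    put(_LWRI, lean + 0.5 * w * s_body - arm_swing, -0.05 * h)
    put(_RHIP, -hw, 0.0)
    put(_LHIP, +hw, 0.0)
    put(_RKNEE, -hw + 0.5 * leg_swing, 0.5 * leg - 0.5 * lift_r)
    put(_LKNEE, +hw - 0.5 * leg_swing, 0.5 * leg - 0.5 * lift_l)
    put(_RANK, -hw + leg_swing, leg - lift_r)
    put(_LANK, +hw - leg_swing, leg - lift_l)

    coords[..., 1] += bob[:, None]
    # walking drift (removed by normalization; kept for bbox realism)
    drift = np.sign(c) * 2.0 * A_leg * params.gait_frequency * t if c != 0 else 0.0 * t
    coords[..., 0] += drift[:, None]
    # place the walker in the image
    coords[..., 0] += FRAME_SIZE[0] * 0.35
    coords[..., 1] += FRAME_SIZE[1] * 0.5

    if defect == "erratic":
        glitch = rng.uniform(-w, w, size=(n_frames, 4, 2))
        coords[:, [_RKNEE, _RANK, _LKNEE, _LANK]] += glitch
    if defect != "static" and params.noise_px > 0:
        coords += rng.normal(0.0, params.noise_px, size=coords.shape)

    a, b = conf_beta
    confs = rng.beta(a, b, size=(n_frames, 18))
    if defect == "low_conf":
        confs = rng.beta(4.0, 36.0, size=(n_frames, 18))
    elif defect == "low_feet_conf":
        confs[:, [_RANK, _LANK]] = rng.beta(4.0, 36.0, size=(n_frames, 2))

    mins = coords.min(axis=1)
    maxs = coords.max(axis=1)
    pad = 0.1 * (maxs - mins)
    bboxes = np.column_stack([mins - pad, maxs - mins + 2 * pad])

    return RawTracklet.from_arrays(
        coords, np.clip(confs, 0.0, 1.0), fps=fps,
        track_id=track_id or f"walker{params.seed}",
        bboxes=bboxes, frame_size=FRAME_SIZE)


@dataclass
class SyntheticCorpus:
    tracklets: list[RawTracklet]
    params: list[WalkerParams]
    attributes: np.ndarray        # (n, 42)
    expected_filter_survivors: int | None = None


def make_pretraining_corpus(n_ids: int, frames_per_id: int = 240,
                            fps: float = 24.0, seed: int = 0) -> SyntheticCorpus:
    """One nominal tracklet per identity, attributes attached."""
    if n_ids < 2:
        raise ValueError("need at least two identities")
    children = np.random.SeedSequence(seed).spawn(n_ids)
    tracklets, params_list, attrs = [], [], []
    for i, child in enumerate(children):
        walker_seed = int(child.generate_state(1)[0] % (2 ** 31 - 1))
        params, attr = sample_walker(walker_seed)
        rng = np.random.default_rng(child)
        tracklets.append(render_tracklet(params, frames_per_id, fps, rng,
                                         track_id=f"id{i:04d}"))
        params_list.append(params)
        attrs.append(attr.values)
    return SyntheticCorpus(tracklets=tracklets, params=params_list,
                           attributes=np.stack(attrs),
                           expected_filter_survivors=n_ids)


def make_filter_fixture(spec: dict[str, int], fps: float = 24.0,
                        seed: int = 0,
                        cfg: PipelineConfig | None = None) -> tuple[list[RawTracklet], int]:
    """Planted-defect fixture: each defect class violates exactly one filter.

    ``spec`` counts tracklets per class in {nominal, too_short, low_conf,
    low_feet_conf, static, erratic}; expected survivor count equals the
    nominal count.
    """
    cfg = cfg or PipelineConfig()
    known = {"nominal", "too_short", "low_conf", "low_feet_conf", "static", "erratic"}
    unknown = set(spec) - known
    if unknown:
        raise ValueError(f"unknown defect classes: {sorted(unknown)}")
    if any(v < 0 for v in spec.values()):
        raise ValueError("counts must be non-negative")

    min_frames = int(np.ceil(cfg.period_T * fps / 24.0))
    nominal_frames = max(2 * min_frames, min_frames + 24)
    ss = np.random.SeedSequence(seed)
    tracklets: list[RawTracklet] = []
    k = 0
    for cls in sorted(spec):
        for _ in range(spec[cls]):
            child = ss.spawn(1)[0]
            walker_seed = int(child.generate_state(1)[0] % (2 ** 31 - 1))
            params, _ = sample_walker(walker_seed)
            rng = np.random.default_rng(child)
            n = nominal_frames
            defect = None
            if cls == "too_short":
                n = max(2, min_frames - rng.integers(1, min_frames // 2 + 1))
            elif cls != "nominal":
                defect = cls
            tracklets.append(render_tracklet(params, int(n), fps, rng,
                                             track_id=f"{cls}{k:03d}", defect=defect))
            k += 1
    order = np.random.default_rng(ss.spawn(1)[0]).permutation(len(tracklets))
    tracklets = [tracklets[i] for i in order]
    return tracklets, spec.get("nominal", 0)
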