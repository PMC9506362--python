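"""Training-time skeleton-sequence augmentations and the two-view sampler.

Contrastive pretraining treats two independent augmentations of the same
tracklet as a positive pair. The suite: random temporal crop of T = 48
frames, horizontal flip with probability 0.5 (mirror x and swap left/right
joints), random pace change (time-axis rescale by a factor drawn uniformly
from ``pace_range``), and Gaussian jitter on the coordinates.

Order matters and is fixed as pace -> crop -> flip -> jitter: the pace
change alters sequence length, so it precedes the fixed-length crop.
Confidences pass through untouched except that a flip carries each joint's
confidence to its mirror slot (a mirrored left joint *is* the right
joint's measurement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton_core import COCO18, JointLayout


@dataclass
class AugmentConfig:
    crop_T: int = 48
    flip_p: float = 0.5
    pace_range: tuple[float, float] = (0.75, 1.5)
    noise_sigma: float = 0.005      # normalized units
    on_short: str = "clamp"         # pace leaving < crop_T frames: clamp factor or error
    layout: JointLayout = COCO18

    def __post_init__(self):
        lo, hi = self.pace_range
        if not (0 < lo <= 1 <= hi):
            raise ValueError("pace_range must satisfy 0 < lo <= 1 <= hi")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.on_short not in ("clamp", "error"):
            raise ValueError("on_short must be 'clamp' or 'error'")


def random_crop(data: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous window of T frames with a uniform start in [0, L - T]."""
    L = data.shape[0]
    if L < T:
        raise ValueError(f"sequence of length {L} shorter than crop T={T}")
    start = int(rng.integers(0, L - T + 1))
    return data[start:start + T].copy()


def horizontal_flip(data: np.ndarray, layout: JointLayout = COCO18) -> np.ndarray:
    """Mirror x and exchange each left/right joint triplet (x, y, c)."""
    out = data.copy()
    out[..., 0] = -out[..., 0]
    for a, b in layout.left_right_pairs:
        out[:, [a, b]] = out[:, [b, a]]
    return out


def random_pace(data: np.ndarray, rng: np.random.Generator,
                pace_range: tuple[float, float] = (0.75, 1.5),
                min_len: int | None = None,
                on_short: str = "clamp") -> np.ndarray:
    """Rescale the time axis by a uniform factor f (f > 1 is faster/shorter).

    Every channel is linearly interpolated; endpoints are preserved. If the
    rescaled length would fall under ``min_len``, the factor is clamped
    (default) or an error raised, per ``on_short``.
    """
    L = data.shape[0]
    if L < 2:
        raise ValueError("pace change needs at least two frames")
    f = float(rng.uniform(*pace_range))
    if min_len is not None:
        f_max = L / min_len
        if f > f_max:
            if on_short == "error":
                raise ValueError(f"pace factor {f:.3f} leaves fewer than {min_len} frames")
            f = f_max
    n_out = max(2, int(round(L / f)))
    t_src = np.arange(L, dtype=float)
    t_out = np.linspace(0.0, L - 1, n_out)
    flat = data.reshape(L, -1)
    out = np.stack([np.interp(t_out, t_src, flat[:, j])
                    for j in range(flat.shape[1])], axis=1)
    return out.reshape((n_out,) + data.shape[1:])


def jitter_joints(data: np.ndarray, sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. N(0, sigma^2) to the x, y channels; confidence untouched."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    out = data.copy()
    if sigma > 0:
        out[..., :2] += rng.normal(0.0, sigma, size=out[..., :2].shape)
    return out


def augment_once(data: np.ndarray, cfg: AugmentConfig,
                 rng: np.random.Generator) -> np.ndarray:
    view = random_pace(data, rng, cfg.pace_range,
                       min_len=cfg.crop_T, on_short=cfg.on_short)
    view = random_crop(view, cfg.crop_T, rng)
    if rng.random() < cfg.flip_p:
        view = horizontal_flip(view, cfg.layout)
    return jitter_joints(view, cfg.noise_sigma, rng)


def two_views(data: np.ndarray, cfg: AugmentConfig,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two independent augmentation draws of one tracklet (a positive pair)."""
    return augment_once(data, cfg, rng), augment_once(data, cfg, rng)
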