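"""Skeleton-sequence data model and geometric normalization.

Sequences come from a 2D pose tracker in the 18-keypoint COCO/OpenPose
layout, one (x, y, confidence) triplet per joint. Before any learning the
pipeline brings every tracklet to a common pace (24 FPS by linear
interpolation of every channel) and a common body frame: each skeleton is
centered at the pelvis (midpoint of the hips) and scaled horizontally by
the shoulder span and vertically by the neck-to-pelvis distance,

    x' = (x - x_pelvis) / max(|x_Rshoulder - x_Lshoulder|, eps)
    y' = (y - y_pelvis) / max(|y_neck   - y_pelvis|,       eps)

which removes position, height and body-scale information while keeping
the movement pattern. Confidences are carried through untouched; a
normalized frame flattens to an 18*3 = 54-dimensional token.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS_GUARD = 1e-6  # denominator guard for degenerate (e.g. perfectly frontal) frames


@dataclass(frozen=True)
class JointLayout:
    """COCO-18 keypoint layout with left/right pairing and leg subsets."""

    names: tuple[str, ...]
    left_right_pairs: tuple[tuple[int, int], ...]
    feet_indices: tuple[int, ...]
    leg_indices: tuple[int, ...]

    def __post_init__(self):
        if len(self.names) != 18:
            raise ValueError("layout must have exactly 18 joints")
        lefts = [a for a, _ in self.left_right_pairs]
        rights = [b for _, b in self.left_right_pairs]
        if len(set(lefts)) != len(lefts) or len(set(rights)) != len(rights):
            raise ValueError("each joint may appear in at most one left/right pair")
        if not set(self.feet_indices) <= set(self.leg_indices):
            raise ValueError("feet indices must be a subset of leg indices")

    def index(self, name: str) -> int:
        return self.names.index(name)


#: OpenPose/COCO-18 ordering.
COCO18 = JointLayout(
    names=(
        "Nose", "Neck",
        "RShoulder", "RElbow", "RWrist",
        "LShoulder", "LElbow", "LWrist",
        "RHip", "RKnee", "RAnkle",
        "LHip", "LKnee", "LAnkle",
        "REye", "LEye", "REar", "LEar",
    ),
    left_right_pairs=((5, 2), (6, 3), (7, 4), (11, 8), (12, 9), (13, 10),
                      (15, 14), (17, 16)),
    feet_indices=(10, 13),
    leg_indices=(9, 10, 12, 13),
)

NOSE, NECK = 0, 1
R_SHOULDER, L_SHOULDER = 2, 5
R_HIP, L_HIP = 8, 11
N_JOINTS = 18
TOKEN_DIM = N_JOINTS * 3  # (x, y, c) per joint


@dataclass
class PoseFrame:
    """One detected skeleton: planar coordinates, confidences, optional box."""

    coords: np.ndarray           # (18, 2)
    conf: np.ndarray             # (18,) in [0, 1]
    bbox: np.ndarray | None = None   # (x, y, w, h)
    frame_index: int = 0
    degenerate: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.conf = np.asarray(self.conf, dtype=float)
        if self.coords.shape != (N_JOINTS, 2):
            raise ValueError(f"coords must be (18, 2), got {self.coords.shape}")
        if self.conf.shape != (N_JOINTS,):
            raise ValueError(f"conf must be (18,), got {self.conf.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.conf < 0) or np.any(self.conf > 1):
            raise ValueError("confidences must lie in [0, 1]")
        if self.bbox is not None:
            self.bbox = np.asarray(self.bbox, dtype=float)


@dataclass
class RawTracklet:
    """One tracked person: an ordered run of frames at a known stream FPS."""

    frames: list[PoseFrame]
    fps: float
    track_id: str = "track"
    frame_size: tuple[float, float] | None = None   # (width, height) px, if known
    crops: list | None = None   # optional aligned image crops (annotation stage)

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    # array views used throughout the pipeline
    @property
    def coords(self) -> np.ndarray:       # (T, 18, 2)
        return np.stack([f.coords for f in self.frames])

    @property
    def confs(self) -> np.ndarray:        # (T, 18)
        return np.stack([f.conf for f in self.frames])

    @property
    def bboxes(self) -> np.ndarray | None:
        if any(f.bbox is None for f in self.frames):
            return None
        return np.stack([f.bbox for f in self.frames])

    @classmethod
    def from_arrays(cls, coords, confs, fps, track_id="track", bboxes=None,
                    frame_indices=None, frame_size=None) -> "RawTracklet":
        coords = np.asarray(coords, dtype=float)
        confs = np.asarray(confs, dtype=float)
        n = coords.shape[0]
        if frame_indices is None:
            frame_indices = np.arange(n)
        frames = [
            PoseFrame(coords[t], confs[t],
                      bbox=None if bboxes is None else bboxes[t],
                      frame_index=int(frame_indices[t]))
            for t in range(n)
        ]
        return cls(frames=frames, fps=fps, track_id=track_id, frame_size=frame_size)


@dataclass
class NormalizedSequence:
    """Pelvis-centered, shoulder/torso-scaled sequence at a reference pace."""

    data: np.ndarray            # (T, 18, 3): x, y normalized; c confidence
    ref_fps: float = 24.0
    track_id: str = "track"
    degenerate: np.ndarray = field(default=None)   # (T,) bool flags

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1:] != (N_JOINTS, 3):
            raise ValueError(f"data must be (T, 18, 3), got {self.data.shape}")
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.data), dtype=bool)
        else:
            self.degenerate = np.asarray(self.degenerate, dtype=bool)

    def __len__(self) -> int:
        return self.data.shape[0]


# ------------------------------------------------------------------ operations

def normalize_frame(frame: PoseFrame) -> PoseFrame:
    """Center a skeleton at the pelvis and scale to unit shoulder/torso.

    The pelvis is the midpoint of the two hips. Degenerate frames (shoulder
    span or torso height below the guard) are flagged, never dropped here —
    filtering is the pipeline's job.
    """
    xy = frame.coords
    pelvis = 0.5 * (xy[L_HIP] + xy[R_HIP])
    shoulder_span = abs(xy[R_SHOULDER, 0] - xy[L_SHOULDER, 0])
    torso_height = abs(xy[NECK, 1] - pelvis[1])
    degenerate = shoulder_span < EPS_GUARD or torso_height < EPS_GUARD
    denom_x = max(shoulder_span, EPS_GUARD)
    denom_y = max(torso_height, EPS_GUARD)
    out = np.empty_like(xy)
    out[:, 0] = (xy[:, 0] - pelvis[0]) / denom_x
    out[:, 1] = (xy[:, 1] - pelvis[1]) / denom_y
    return PoseFrame(out, frame.conf.copy(), bbox=None if frame.bbox is None
                     else frame.bbox.copy(),
                     frame_index=frame.frame_index, degenerate=degenerate)


def normalize_sequence(track: RawTracklet) -> NormalizedSequence:
    """Apply :func:`normalize_frame` to every frame of a tracklet."""
    if len(track) == 0:
        raise ValueError("cannot normalize an empty tracklet")
    frames = [normalize_frame(f) for f in track.frames]
    data = np.stack([np.column_stack([f.coords, f.conf]) for f in frames])
    flags = np.array([f.degenerate for f in frames], dtype=bool)
    return NormalizedSequence(data=data, ref_fps=track.fps,
                              track_id=track.track_id, degenerate=flags)


def resample_to_reference_fps(track: RawTracklet, ref_fps: float = 24.0) -> RawTracklet:
    """Unify pace: linearly interpolate every channel onto a ref_fps time grid.

    The output covers the same wall-clock duration (n-1)/fps; resampling at
    the source FPS is the identity.
    """
    n = len(track)
    if n < 2:
        raise ValueError("resampling needs at least two frames")
    duration = (n - 1) / track.fps
    n_out = int(np.floor(duration * ref_fps + 1e-9)) + 1
    t_src = np.arange(n) / track.fps
    t_out = np.arange(n_out) / ref_fps
    coords = track.coords
    confs = track.confs
    flat = coords.reshape(n, -1)
    out_coords = np.stack([np.interp(t_out, t_src, flat[:, j])
                           for j in range(flat.shape[1])], axis=1).reshape(n_out, N_JOINTS, 2)
    out_confs = np.stack([np.interp(t_out, t_src, confs[:, j])
                          for j in range(N_JOINTS)], axis=1)
    bboxes = track.bboxes
    out_bboxes = None
    if bboxes is not None:
        out_bboxes = np.stack([np.interp(t_out, t_src, bboxes[:, j])
                               for j in range(4)], axis=1)
    return RawTracklet.from_arrays(out_coords, out_confs, fps=ref_fps,
                                   track_id=track.track_id, bboxes=out_bboxes,
                                   frame_size=track.frame_size)


def center_crop(seq: NormalizedSequence, T: int = 48) -> NormalizedSequence:
    """Deterministic middle crop of T frames (evaluation protocol)."""
    L = len(seq)
    if L < T:
        raise ValueError(f"sequence of length {L} is shorter than crop T={T}")
    start = (L - T) // 2
    return NormalizedSequence(data=seq.data[start:start + T].copy(),
                              ref_fps=seq.ref_fps, track_id=seq.track_id,
                              degenerate=seq.degenerate[start:start + T].copy())


def flatten(seq: NormalizedSequence) -> np.ndarray:
    """T x 54 token matrix: per frame the (x, y, c) triplets in layout order."""
    return seq.data.reshape(len(seq), TOKEN_DIM).copy()


def unflatten(tokens: np.ndarray, ref_fps: float = 24.0,
              track_id: str = "track") -> NormalizedSequence:
    tokens = np.asarray(tokens, dtype=float)
    if tokens.ndim != 2 or tokens.shape[1] != TOKEN_DIM:
        raise ValueError(f"tokens must be (T, {TOKEN_DIM})")
    return NormalizedSequence(data=tokens.reshape(-1, N_JOINTS, 3).copy(),
                              ref_fps=ref_fps, track_id=track_id)


def mean_leg_speed(seq: NormalizedSequence,
                   layout: JointLayout = COCO18) -> float:
    """Average per-frame Euclidean displacement of the leg joints.

    Units are normalized coordinates per frame; computed over knees and
    ankles. This statistic separates standing people (near zero) from
    tracking glitches (erratically large) and drives the pipeline's
    keep-band filter.
    """
    if len(seq) < 2:
        raise ValueError("leg speed needs at least two frames")
    legs = seq.data[:, list(layout.leg_indices), :2]
    disp = np.linalg.norm(np.diff(legs, axis=0), axis=2)   # (T-1, n_leg_joints)
    return float(disp.mean())
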