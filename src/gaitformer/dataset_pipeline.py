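"""Corpus construction: confidence / duration / leg-speed filtering.

The construction chain, in order, is:

1. remove frames whose mean joint confidence is below 0.5,
2. remove frames whose mean feet (ankle) confidence is below 0.4,
3. drop tracklets shorter than T * fps / 24 frames (duration in source-FPS
   units; T = 48 frames, about two gait cycles at the 24 FPS reference),
4. linearly resample to the 24 FPS reference pace,
5. normalize every skeleton (pelvis-centered, shoulder/torso-scaled),
6. keep only sequences whose mean leg speed lies in [0.0015, 0.09]
   normalized units/frame (standing people below, tracking glitches above).

"Below" is strict everywhere: a value exactly at a threshold is kept.
Frame removal can open gaps inside a tracklet; short gaps (up to
``max_gap_fill`` frames) are refilled by linear interpolation, longer gaps
split the tracklet into independent segments so that temporal continuity
is never faked across a long occlusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .skeleton_core import (COCO18, JointLayout, NormalizedSequence, RawTracklet,
                            mean_leg_speed, normalize_sequence,
                            resample_to_reference_fps)


@dataclass
class PipelineConfig:
    min_mean_conf: float = 0.5
    min_feet_conf: float = 0.4
    period_T: int = 48
    ref_fps: float = 24.0
    leg_speed_lo: float = 0.0015
    leg_speed_hi: float = 0.09
    max_gap_fill: int = 12
    layout: JointLayout = COCO18

    def __post_init__(self):
        if not (0.0 <= self.min_mean_conf <= 1.0 and 0.0 <= self.min_feet_conf <= 1.0):
            raise ValueError("confidence thresholds must lie in [0, 1]")
        if self.leg_speed_lo >= self.leg_speed_hi:
            raise ValueError("leg_speed_lo must be below leg_speed_hi")
        if self.period_T <= 0:
            raise ValueError("period_T must be positive")


@dataclass
class GaitDataset:
    """Filtered corpus: one normalized sequence per surviving tracklet.

    Each tracklet is treated as a unique identity; ``stats`` ledgers how
    many inputs each filter stage removed.
    """

    sequences: list[NormalizedSequence]
    ids: list[str]
    attributes: np.ndarray | None = None   # (n, 42) soft labels, optional
    stats: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.sequences) != len(self.ids):
            raise ValueError("sequences and ids must align")

    def __len__(self) -> int:
        return len(self.sequences)


# ------------------------------------------------------------------ internals

def _segments_from_mask(track: RawTracklet, keep: np.ndarray,
                        max_gap_fill: int) -> list[RawTracklet]:
    """Apply a frame keep-mask: fill short interior gaps, split on long ones."""
    n = len(track)
    if not keep.any():
        return []
    kept_idx = np.flatnonzero(keep)
    # group kept indices into runs separated by gaps > max_gap_fill
    groups: list[list[int]] = [[int(kept_idx[0])]]
    for i in kept_idx[1:]:
        gap = int(i) - groups[-1][-1] - 1
        if gap > max_gap_fill:
            groups.append([int(i)])
        else:
            groups[-1].append(int(i))

    coords, confs, bboxes = track.coords, track.confs, track.bboxes
    out: list[RawTracklet] = []
    for g, idx in enumerate(groups):
        idx = np.asarray(idx)
        span = np.arange(idx[0], idx[-1] + 1)
        if len(idx) == len(span):
            sel_coords, sel_confs = coords[idx], confs[idx]
            sel_boxes = None if bboxes is None else bboxes[idx]
        else:
            # refill removed interior frames by per-channel linear interpolation
            def interp(channel: np.ndarray) -> np.ndarray:
                flat = channel.reshape(len(channel), -1)
                out_flat = np.stack([np.interp(span, idx, flat[idx, j])
                                     for j in range(flat.shape[1])], axis=1)
                return out_flat.reshape((len(span),) + channel.shape[1:])

            sel_coords = interp(coords)
            sel_confs = interp(confs)
            sel_boxes = None if bboxes is None else interp(bboxes)
        tid = track.track_id if len(groups) == 1 else f"{track.track_id}#{g}"
        out.append(RawTracklet.from_arrays(sel_coords, sel_confs, fps=track.fps,
                                           track_id=tid, bboxes=sel_boxes,
                                           frame_size=track.frame_size))
    return out


def _drop_frames(track: RawTracklet, keep: np.ndarray,
                 max_gap_fill: int) -> list[RawTracklet]:
    return _segments_from_mask(track, keep, max_gap_fill)


# ------------------------------------------------------------------ operations

def drop_low_confidence_frames(track: RawTracklet, thr: float = 0.5,
                               max_gap_fill: int = 12) -> list[RawTracklet]:
    """Remove frames whose mean 18-joint confidence is below ``thr``.

    Returns the surviving segments (possibly none): interior gaps up to
    ``max_gap_fill`` frames are refilled by interpolation, longer gaps
    split the tracklet.
    """
    keep = track.confs.mean(axis=1) >= thr
    return _drop_frames(track, keep, max_gap_fill)


def drop_low_feet_confidence_frames(track: RawTracklet, thr: float = 0.4,
                                    max_gap_fill: int = 12,
                                    layout: JointLayout = COCO18) -> list[RawTracklet]:
    """Remove frames whose mean ankle confidence is below ``thr``."""
    keep = track.confs[:, list(layout.feet_indices)].mean(axis=1) >= thr
    return _drop_frames(track, keep, max_gap_fill)


def is_long_enough(track: RawTracklet, cfg: PipelineConfig) -> bool:
    """Duration filter in source-FPS units: at least T * fps / 24 frames."""
    return len(track) >= cfg.period_T * track.fps / 24.0


def passes_leg_speed(seq: NormalizedSequence, cfg: PipelineConfig) -> bool:
    """Keep-band on mean leg speed: lo <= speed <= hi (equality kept)."""
    speed = mean_leg_speed(seq, cfg.layout)
    return cfg.leg_speed_lo <= speed <= cfg.leg_speed_hi


def build_dataset(tracks: list[RawTracklet],
                  cfg: PipelineConfig | None = None) -> GaitDataset:
    """Run the full construction chain and ledger per-stage removals.

    Stats keys: ``low_conf`` / ``low_feet_conf`` (tracklet fully consumed by
    a confidence filter), ``short`` (duration filter), ``speed`` (leg-speed
    band). A tracklet split into segments is accounted per segment from the
    duration stage onward.
    """
    cfg = cfg or PipelineConfig()
    stats = {"low_conf": 0, "low_feet_conf": 0, "short": 0, "speed": 0}
    sequences: list[NormalizedSequence] = []
    ids: list[str] = []

    for track in tracks:
        segs = drop_low_confidence_frames(track, cfg.min_mean_conf, cfg.max_gap_fill)
        if not segs:
            stats["low_conf"] += 1
            continue
        segs2: list[RawTracklet] = []
        for seg in segs:
            segs2.extend(drop_low_feet_confidence_frames(
                seg, cfg.min_feet_conf, cfg.max_gap_fill, cfg.layout))
        if not segs2:
            stats["low_feet_conf"] += 1
            continue
        for seg in segs2:
            if not is_long_enough(seg, cfg):
                stats["short"] += 1
                continue
            resampled = resample_to_reference_fps(seg, cfg.ref_fps)
            normalized = normalize_sequence(resampled)
            if not passes_leg_speed(normalized, cfg):
                stats["speed"] += 1
                continue
            sequences.append(normalized)
            ids.append(seg.track_id)

    return GaitDataset(sequences=sequences, ids=ids, stats=stats)
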