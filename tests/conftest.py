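import numpy as np
import pytest

from gaitformer.skeleton_core import (COCO18, N_JOINTS, PoseFrame, RawTracklet,
                                      NormalizedSequence)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pose_frame(rng, frame_index=0, scale=50.0, offset=(300.0, 200.0)):
    """A random but non-degenerate skeleton frame (distinct shoulders/torso)."""
    coords = rng.normal(0.0, scale, size=(N_JOINTS, 2)) + np.asarray(offset)
    # guarantee usable normalization denominators
    coords[2, 0] = offset[0] - scale          # RShoulder
    coords[5, 0] = offset[0] + scale          # LShoulder
    coords[1, 1] = offset[1] - 2 * scale      # Neck above ...
    coords[8, 1] = coords[11, 1] = offset[1]  # ... the hips
    conf = rng.uniform(0.3, 1.0, size=N_JOINTS)
    return PoseFrame(coords, conf, frame_index=frame_index)


@pytest.fixture
def walking_tracklet(rng):
    """A calibrated synthetic walker tracklet (120 frames at 24 FPS)."""
    from gaitformer.synthetic_data import render_tracklet, sample_walker

    params, _ = sample_walker(777)
    return render_tracklet(params, 120, 24.0, np.random.default_rng(0))


@pytest.fixture
def normalized_walker(walking_tracklet):
    from gaitformer.skeleton_core import normalize_sequence

    return normalize_sequence(walking_tracklet)


@pytest.fixture(scope="session")
def tiny_model_config():
    from gaitformer.gaitformer_model import ModelConfig

    return ModelConfig(n_layers=2, d_model=64, n_heads=4, ff_dim=128,
                       emb_dim=64, proj_dim=32)
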