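import numpy as np
import pytest

from conjuflow.io import FrameSequence
from conjuflow.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """A full default scene (motion, blur, noise) shared across tests."""
    cfg = SceneConfig(seed=3)
    seq, gt = generate_scene(cfg)
    return cfg, seq, gt


@pytest.fixture(scope="session")
def still_scene():
    """A motion-free, blur-free scene with flowing clusters (SNR 10)."""
    cfg = SceneConfig(seed=5, saccades={}, drift_amplitude_px=0.0, blur_frames=())
    seq, gt = generate_scene(cfg)
    return cfg, seq, gt


def make_sequence(frames, fps=25.0, um_px=3.45 / 3.798):
    return FrameSequence(np.asarray(frames, dtype=float), fps=fps,
                         microns_per_pixel=um_px)
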