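import numpy as np
import pytest

from cardiomotion import (FrangiSegmenter, MotionAmplitude, MotionSpec,
                          generate_vessel_tree, render_sequence)


@pytest.fixture(scope="session")
def headline_runs():
    """Full default pipeline (75-frame combined-motion phantom) on three
    seeds; shared by the headline bound and the stage-isolation check."""
    from cardiomotion.pipeline import default_phantom_run
    return {seed: default_phantom_run(seed) for seed in (0, 1, 2)}


@pytest.fixture(scope="session")
def default_tree():
    return generate_vessel_tree(0, n_branches=5, canvas_size=(256, 256))


@pytest.fixture(scope="session")
def both_motion_sequence(default_tree):
    """75-frame combined cardiac+respiratory sequence with ground truth."""
    return render_sequence(default_tree, MotionSpec(rng_seed=100))


@pytest.fixture(scope="session")
def noise_free_sequence(default_tree):
    return render_sequence(default_tree, MotionSpec(rng_seed=100), noise_sd=0.0)


@pytest.fixture(scope="session")
def segmenter():
    return FrangiSegmenter()


@pytest.fixture(scope="session")
def segmented_pair(both_motion_sequence, segmenter):
    """Centerlines of the first two frames (segmentation is the slow part)."""
    frames = both_motion_sequence.frames.frames
    return (segmenter.transform_frame(frames[0]),
            segmenter.transform_frame(frames[1]))


@pytest.fixture(scope="session")
def wavy_centerline():
    """100-point noiseless synthetic centerline used by CPD oracles."""
    t = np.linspace(0.0, 1.0, 100)
    return np.column_stack([100 + 80 * t, 100 + 30 * np.sin(4 * t)])


@pytest.fixture
def translation_only_spec():
    """Pure integer-pixel drift: rasterization is exactly equivariant."""
    return MotionSpec(
        cardiac_amplitude=MotionAmplitude(0.0, 0.0, 0.0),
        respiratory_amplitude=MotionAmplitude(0.0, 0.0, 0.0),
        drift_px_per_frame=(3.0, 0.0),
        n_frames=12,
        rng_seed=3,
    )
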