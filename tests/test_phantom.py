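import numpy as np
import pytest

from cardiomotion import (MotionAmplitude, MotionSpec, generate_vessel_tree,
                          motion_at, render_sequence)


class TestVesselTree:
    def test_single_branch_inside_canvas(self):
        tree = generate_vessel_tree(0, n_branches=1, canvas_size=(256, 256))
        pts = tree.all_points
        assert len(tree.segments) == 1
        assert pts[:, 0].min() >= 0 and pts[:, 0].max() <= 255
        assert pts[:, 1].min() >= 0 and pts[:, 1].max() <= 255

    def test_deterministic_for_seed(self):
        a = generate_vessel_tree(7, n_branches=4)
        b = generate_vessel_tree(7, n_branches=4)
        assert len(a.segments) == len(b.segments)
        for s1, s2 in zip(a.segments, b.segments):
            assert np.array_equal(s1, s2)

    def test_five_branch_tree_is_connected(self):
        """Breadth-first search over segment adjacency reaches every branch."""
        tree = generate_vessel_tree(1, n_branches=5, canvas_size=(512, 512))
        n = len(tree.segments)
        assert n == 5
        adj = {i: set() for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(
                    tree.segments[i][:, None, :] - tree.segments[j][None, :, :],
                    axis=2).min()
                if d < 1.0:  # touching segments
                    adj[i].add(j)
                    adj[j].add(i)
        seen, queue = {0}, [0]
        while queue:
            for nb in adj[queue.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        assert seen == set(range(n))

    def test_canvas_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_vessel_tree(0, n_branches=1, canvas_size=(20, 20))


class TestMotionAt:
    def test_identity_at_frame_zero(self):
        spec = MotionSpec()
        assert np.allclose(motion_at(0, spec, (128.0, 128.0)), np.eye(3),
                           atol=1e-15)

    def test_cardiac_periodicity(self):
        # cardiac period 2 s at 7.5 fps -> exactly 15 frames per cycle
        spec = MotionSpec(mode="cardiac_only", cardiac_period=2.0, n_frames=40)
        m_a = motion_at(3, spec, (100.0, 100.0))
        m_b = motion_at(18, spec, (100.0, 100.0))
        assert np.abs(m_a - m_b).max() < 1e-9

    def test_both_mode_is_product_of_components(self):
        """Composition equals independently recomputed resp @ cardiac."""
        spec = MotionSpec(mode="both", rng_seed=5)
        center = (120.0, 130.0)
        c_spec = MotionSpec(mode="cardiac_only", rng_seed=5)
        r_spec = MotionSpec(mode="respiratory_only", rng_seed=5)
        for t in (1, 7, 33, 74):
            combined = motion_at(t, spec, center)
            product = motion_at(t, r_spec, center) @ motion_at(t, c_spec, center)
            assert np.abs(combined - product).max() < 1e-12

    def test_frame_index_out_of_range(self):
        with pytest.raises(ValueError):
            motion_at(75, MotionSpec(n_frames=75))

    def test_irregularity_burst_adds_translation(self):
        from cardiomotion import MotionBurst
        quiet = MotionSpec(mode="cardiac_only")
        noisy = MotionSpec(mode="cardiac_only", irregularity=[
            MotionBurst(onset_frame=10, duration_frames=6, magnitude_mm=2.0)])
        center = (128.0, 128.0)
        inside = motion_at(13, noisy, center) @ np.linalg.inv(
            motion_at(13, quiet, center))
        assert np.abs(inside[:2, :2] - np.eye(2)).max() < 1e-12
        assert np.abs(inside[:2, 2]).max() > 1.0  # burst active
        outside = motion_at(30, noisy, center)
        assert np.abs(outside - motion_at(30, quiet, center)).max() < 1e-12


class TestRenderSequence:
    def test_transform_count(self, both_motion_sequence):
        assert len(both_motion_sequence.true_transforms) == 74
        assert both_motion_sequence.frames.frames.shape == (75, 256, 256)

    def test_relative_transforms_compose_to_absolute(self, both_motion_sequence):
        spec = both_motion_sequence.spec
        center = tuple(both_motion_sequence.tree.centroid)
        cum = np.eye(3)
        for t, rel in enumerate(both_motion_sequence.true_transforms):
            cum = rel @ cum
            expected = motion_at(t + 1, spec, center)
            assert np.abs(cum - expected).max() < 1e-9

    def test_static_noise_free_frames_identical(self, default_tree):
        spec = MotionSpec(
            cardiac_amplitude=MotionAmplitude(0, 0, 0),
            respiratory_amplitude=MotionAmplitude(0, 0, 0),
            n_frames=4)
        seq = render_sequence(default_tree, spec, noise_sd=0.0)
        for t in range(1, 4):
            assert np.array_equal(seq.frames.frames[0], seq.frames.frames[t])
            assert np.array_equal(seq.true_transforms[t - 1], np.eye(3))

    def test_pure_translation_ground_truth(self, default_tree,
                                           translation_only_spec):
        seq = render_sequence(default_tree, translation_only_spec)
        for m in seq.true_transforms:
            assert np.allclose(m[:2, :2], np.eye(2), atol=1e-12)
            assert np.allclose(m[:2, 2], (3.0, 0.0), atol=1e-9)

    def test_reproducible_for_seed(self, default_tree):
        spec = MotionSpec(n_frames=6, rng_seed=11)
        a = render_sequence(default_tree, spec)
        b = render_sequence(default_tree, spec)
        assert np.array_equal(a.frames.frames, b.frames.frames)

    def test_escaping_motion_names_frame(self, default_tree):
        spec = MotionSpec(respiratory_amplitude=MotionAmplitude(80.0, 0, 0),
                          n_frames=20)
        with pytest.raises(ValueError, match="frame"):
            render_sequence(default_tree, spec)

    def test_mode_spectral_separation(self, default_tree):
        """cardiac_only leaves no power in the respiratory DFT bin and
        vice versa (75 frames at 7.5 fps = 10 cardiac / 2 resp cycles)."""
        center = tuple(default_tree.centroid)
        for mode, silent_bin in (("cardiac_only", 2), ("respiratory_only", 10)):
            spec = MotionSpec(mode=mode, n_frames=76)
            tx = np.array([motion_at(t, spec, center)[0, 2] for t in range(75)])
            power = np.abs(np.fft.rfft(tx)) ** 2
            total = power[1:].sum()
            assert power[silent_bin] < 1e-12 * total
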