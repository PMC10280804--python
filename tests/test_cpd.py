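import numpy as np
import pytest

from cardiomotion import (AffineCPD, AffineParams, CPDConfig, apply_transform,
                          compose_affine, cpd_affine, register_sequence)
from cardiomotion.cpd import RegistrationError


def random_recoverable_affine(rng, center):
    """Scale in [0.9, 1.1], |rotation| <= 10 deg, |translation| <= 10 px."""
    return compose_affine(AffineParams(
        sx=rng.uniform(0.9, 1.1), sy=rng.uniform(0.9, 1.1),
        theta=np.deg2rad(rng.uniform(-10, 10)),
        cx=center[0], cy=center[1],
        x=center[0] + rng.uniform(-10, 10),
        y=center[1] + rng.uniform(-10, 10)))


class TestCPDAffine:
    def test_identity_recovered_for_identical_sets(self, wavy_centerline):
        res = cpd_affine(wavy_centerline, wavy_centerline.copy(),
                         CPDConfig(w=0.0))
        assert np.abs(res.transform - np.eye(3)).max() < 1e-6

    def test_known_affine_recovered(self, wavy_centerline):
        rng = np.random.default_rng(3)
        G = random_recoverable_affine(rng, wavy_centerline.mean(axis=0))
        target = apply_transform(G, wavy_centerline[::2])  # 50 points
        res = cpd_affine(wavy_centerline[::2], target, CPDConfig(w=0.0))
        assert np.abs(res.transform - G).max() < 1e-3

    def test_recovery_with_spurious_points(self, wavy_centerline):
        rng = np.random.default_rng(4)
        G = random_recoverable_affine(rng, wavy_centerline.mean(axis=0))
        target = apply_transform(G, wavy_centerline)
        spurious = rng.uniform(80, 220, size=(10, 2))  # 10% outliers
        res = cpd_affine(wavy_centerline, np.vstack([target, spurious]),
                         CPDConfig(w=0.1))
        assert np.abs(res.transform - G).max() < 5e-2

    def test_objective_non_increasing(self, wavy_centerline, segmented_pair):
        rng = np.random.default_rng(5)
        cases = [
            (wavy_centerline,
             apply_transform(random_recoverable_affine(
                 rng, wavy_centerline.mean(axis=0)), wavy_centerline)),
            (segmented_pair[0].points, segmented_pair[1].points),
        ]
        for src, tgt in cases:
            est = AffineCPD(w=0.1).fit(src, tgt)
            h = np.array(est.objective_history_)
            slack = 1e-9 * np.maximum(1.0, np.abs(h[:-1]))
            assert np.all(np.diff(h) <= slack)

    def test_translation_equivariance(self, wavy_centerline):
        rng = np.random.default_rng(6)
        G = random_recoverable_affine(rng, wavy_centerline.mean(axis=0))
        target = apply_transform(G, wavy_centerline)
        base = cpd_affine(wavy_centerline, target, CPDConfig(w=0.0)).transform
        shift = np.array([17.0, -9.0])
        moved = cpd_affine(wavy_centerline + shift, target + shift,
                           CPDConfig(w=0.0)).transform
        assert np.abs(moved[:2, :2] - base[:2, :2]).max() < 1e-6
        expected_t = base[:2, 2] + shift - base[:2, :2] @ shift
        assert np.abs(moved[:2, 2] - expected_t).max() < 1e-6

    def test_collinear_source_rejected(self):
        line = np.column_stack([np.linspace(0, 50, 30), np.linspace(0, 25, 30)])
        with pytest.raises(RegistrationError, match="collinear"):
            cpd_affine(line, line + 2.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(RegistrationError):
            cpd_affine(np.array([[0.0, 0], [1, 1]]), np.array([[0.0, 0], [1, 1]]))

    def test_oracle_recovery_rate(self, wavy_centerline):
        """>= 95 of 100 seeded random affines recovered to 1e-2 elementwise
        on 100-point sets."""
        rng = np.random.default_rng(2024)
        center = wavy_centerline.mean(axis=0)
        hits = 0
        for _ in range(100):
            G = random_recoverable_affine(rng, center)
            res = cpd_affine(wavy_centerline, apply_transform(G, wavy_centerline),
                             CPDConfig(w=0.0))
            hits += np.abs(res.transform - G).max() <= 1e-2
        assert hits >= 95


class TestRegisterSequence:
    def test_pairwise_count_and_direction(self, wavy_centerline):
        shift = np.array([2.0, 1.0])
        frames = [wavy_centerline + i * shift for i in range(6)]
        transforms = register_sequence(frames, CPDConfig(w=0.0))
        assert len(transforms) == 5
        for m in transforms:  # forward: frame t onto frame t+1
            assert np.abs(m[:2, 2] - shift).max() < 1e-3
        backward = register_sequence(frames, CPDConfig(w=0.0),
                                     direction="backward")
        for m in backward:
            assert np.abs(m[:2, 2] + shift).max() < 1e-3

    def test_static_sequence_identity(self, wavy_centerline):
        frames = [wavy_centerline.copy() for _ in range(4)]
        for m in register_sequence(frames, CPDConfig(w=0.0)):
            assert np.abs(m - np.eye(3)).max() < 1e-6

    def test_failure_reports_frame_index(self, wavy_centerline):
        line = np.column_stack([np.linspace(0, 50, 30), np.zeros(30)])
        with pytest.raises(RegistrationError, match=r"\(1, 2\)"):
            register_sequence([wavy_centerline, line, wavy_centerline])

    def test_needs_two_frames(self, wavy_centerline):
        with pytest.raises(ValueError):
            register_sequence([wavy_centerline])

    def test_noise_free_translation_sequence_recovers_truth(
            self, default_tree, translation_only_spec, segmenter):
        """Integer-pixel drift renders to exactly shifted frames, so the
        registered transforms must match the simulator ground truth."""
        from cardiomotion import render_sequence
        seq = render_sequence(default_tree, translation_only_spec, noise_sd=0.0)
        centerlines = segmenter.transform(seq.frames.frames[:5])
        transforms = register_sequence(centerlines)
        err = [np.abs(m - g).mean() for m, g
               in zip(transforms, seq.true_transforms)]
        assert np.mean(err) <= 1e-2
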