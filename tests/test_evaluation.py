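import numpy as np
import pytest

from cardiomotion import (distance_transform_error, evaluate_sequence,
                          mae_table, matrix_to_tp)


def brute_force_dt(mask, points, spacing):
    """O(N*M) nearest-centerline-pixel mean distance oracle."""
    cl = np.argwhere(mask)[:, ::-1].astype(float)  # (x, y)
    d = np.linalg.norm(points[:, None, :] - cl[None, :, :], axis=2).min(axis=1)
    return d.mean() * spacing


class TestMAE:
    def test_zero_for_perfect_prediction(self):
        a = np.random.default_rng(0).normal(size=(4, 5, 6))
        assert np.array_equal(mae_table(a, a), np.zeros(6))

    def test_constant_offset(self):
        a = np.zeros((3, 5, 6))
        assert np.allclose(mae_table(a + 0.5, a), 0.5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        p, t = rng.normal(size=(10, 5, 6)), rng.normal(size=(10, 5, 6))
        expected = np.array([np.abs(p[..., j] - t[..., j]).mean()
                             for j in range(6)])
        assert np.allclose(mae_table(p, t), expected, atol=1e-15)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae_table(np.zeros((2, 5, 6)), np.zeros((3, 5, 6)))


class TestDTError:
    def test_zero_on_centerline(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10, 5:25] = True
        pts = np.column_stack([np.arange(5, 25), np.full(20, 10)])
        err, oob = distance_transform_error(mask, pts, 0.35)
        assert err == 0.0 and oob == 0

    def test_perpendicular_shift_arithmetic(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30, 8:56] = True  # straight line along y=30
        pts = np.column_stack([np.arange(8, 56), np.full(48, 33.0)])  # +3 px
        err, _ = distance_transform_error(mask, pts, 0.35)
        assert abs(err - 3 * 0.35) < 1e-9

    def test_matches_brute_force_oracle(self):
        """Sampled-DT error equals exhaustive nearest-neighbor distance on
        50 random instances (points at integer positions)."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            mask = np.zeros((48, 48), dtype=bool)
            idx = rng.choice(48 * 48, size=rng.integers(5, 200), replace=False)
            mask[np.unravel_index(idx, mask.shape)] = True
            pts = rng.integers(0, 48, size=(rng.integers(5, 200), 2)).astype(float)
            fast, _ = distance_transform_error(mask, pts, 0.35)
            slow = brute_force_dt(mask, pts, 0.35)
            assert abs(fast - slow) <= 1e-9 * max(slow, 1.0)

    def test_out_of_bounds_clipped_and_counted(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, 8] = True
        pts = np.array([[8.0, 8.0], [40.0, 8.0]])
        err, oob = distance_transform_error(mask, pts, 1.0)
        assert oob == 1
        assert err == pytest.approx((0.0 + 7.0) / 2)

    def test_error_strictly_grows_with_offset(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30, 4:60] = True
        base = np.column_stack([np.arange(4, 60), np.full(56, 30.0)])
        errs = [distance_transform_error(mask, base + [0.0, dy], 1.0)[0]
                for dy in (0, 2, 5, 9)]
        assert all(b > a for a, b in zip(errs, errs[1:]))

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            distance_transform_error(np.zeros((8, 8), dtype=bool),
                                     np.array([[1.0, 1.0]]), 0.35)


class TestEvaluateSequence:
    def _line_frames(self, n_frames, shift_per_frame=3.0):
        """Horizontal centerline translating down (perpendicular to
        itself) by 3 px / frame."""
        frames, points = [], []
        for t in range(n_frames):
            mask = np.zeros((256, 64), dtype=bool)
            y0 = 10 + int(round(shift_per_frame * t))
            mask[y0, 10:50] = True
            frames.append(mask)
            points.append(np.argwhere(mask)[:, ::-1].astype(float))
        return frames, points

    def test_perfect_transforms_give_zero_error(self):
        frames, points = self._line_frames(25)
        shift = np.eye(3)
        shift[1, 2] = 3.0
        W, P, K = 15, 5, 3
        predicted = np.tile(matrix_to_tp(shift), (K, P, 1))
        rep = evaluate_sequence(points, frames, predicted,
                                window_starts=[0, 1, 2], W=W,
                                pixel_spacing=0.35)
        assert rep.mean_dt_error_mm == pytest.approx(0.0)
        assert rep.mean_dt_error_mm == pytest.approx(
            np.mean(rep.per_frame_dt_error))

    def test_identity_prediction_error_grows_linearly_with_horizon(self):
        """Predicting no motion on a 3 px/frame drift: the error at
        horizon h is 3*h px, i.e. 3*h*0.35 mm."""
        frames, points = self._line_frames(25)
        predicted = np.tile(matrix_to_tp(np.eye(3)), (2, 5, 1))
        rep = evaluate_sequence(points, frames, predicted,
                                window_starts=[0, 1], W=15,
                                pixel_spacing=0.35)
        for h, err in enumerate(rep.per_step_dt_error, start=1):
            # every point sits exactly 3*h px from the drifted line
            assert err == pytest.approx(3.0 * h * 0.35, rel=1e-9)

    def test_missing_frames_skipped_and_reported(self):
        frames, points = self._line_frames(22)
        predicted = np.tile(matrix_to_tp(np.eye(3)), (2, 5, 1))
        rep = evaluate_sequence(points, frames, predicted,
                                window_starts=[1, 2], W=15,
                                pixel_spacing=0.35)
        assert rep.skipped_frames == [22]
        assert len(rep.per_frame_dt_error) == 9
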