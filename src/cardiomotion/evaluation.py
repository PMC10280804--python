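"""Scoring of predicted motion against registration ground truth.

Two complementary error measures:

* per-parameter mean absolute error (MAE) between predicted and reference
  TP vectors — translations in pixels, linear-part entries unitless;
* the distance-transform (DT) centerline error in millimetres: the
  Euclidean distance transform of the reference centerline image assigns
  every pixel its distance to the nearest centerline pixel; sampling it at
  the predicted (transformed) centerline points and averaging, then
  multiplying by the pixel spacing, gives a geometric prediction error in
  physical units.

Multi-step forecasts are scored by composing the predicted per-step
transforms cumulatively from the last observed frame, so the error at
horizon h reflects h accumulated prediction steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as _ndi

from .affine import apply_transform, tp_to_matrix

__all__ = [
    "EvaluationReport",
    "mae_table",
    "distance_transform_error",
    "evaluate_sequence",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Aggregated sequence-level scores.

    ``per_parameter_mae`` is ordered (Tx, Ty, A00, A01, A10, A11);
    ``per_frame_dt_error`` holds one mm value per scored (window, horizon)
    pair; ``per_step_dt_error`` averages by horizon step 1..P.
    """

    per_parameter_mae: np.ndarray | None
    mean_dt_error_mm: float | None
    per_frame_dt_error: list[float] = field(default_factory=list)
    per_step_dt_error: list[float] = field(default_factory=list)
    pixel_spacing: float | None = None
    n_out_of_bounds: int = 0
    skipped_frames: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "per_parameter_mae": None if self.per_parameter_mae is None
            else {k: float(v) for k, v in zip(
                ("Tx", "Ty", "A00", "A01", "A10", "A11"),
                self.per_parameter_mae)},
            "mean_dt_error_mm": self.mean_dt_error_mm,
            "per_step_dt_error_mm": [float(v) for v in self.per_step_dt_error],
            "pixel_spacing_mm_per_px": self.pixel_spacing,
            "n_out_of_bounds_points": self.n_out_of_bounds,
            "skipped_frames": list(self.skipped_frames),
        }


def mae_table(predicted: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Column-wise MAE over all windows and horizon steps.

    ``predicted`` and ``truth`` are (K, P, 6) (or (T, 6)) on the same
    scale; returns six scalars ordered (Tx, Ty, A00, A01, A10, A11).
    """
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    if predicted.shape[-1] != 6:
        raise ValueError("last axis must hold the 6 TP parameters")
    return np.abs(predicted - truth).reshape(-1, 6).mean(axis=0)


def distance_transform_error(
    true_centerline: np.ndarray,
    predicted_points: np.ndarray,
    pixel_spacing: float,
    interpolation: str = "nearest",
) -> tuple[float, int]:
    """Mean DT value at the predicted points, in millimetres.

    Points falling outside the image are clipped to its border, counted,
    and reported alongside the error.  ``interpolation`` selects how the
    DT image is sampled at sub-pixel point locations: ``"nearest"``
    (rounded pixel lookup, default) or ``"bilinear"``.
    """
    mask = np.asarray(true_centerline, dtype=bool)
    if not mask.any():
        raise ValueError("true centerline image is empty")
    pts = np.atleast_2d(np.asarray(predicted_points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("no predicted points to score")
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive (mm / pixel)")
    h, w = mask.shape
    dt = _ndi.distance_transform_edt(~mask)

    x, y = pts[:, 0], pts[:, 1]
    oob = int(np.count_nonzero((x < 0) | (x > w - 1) | (y < 0) | (y > h - 1)))
    if oob:
        logger.warning("%d predicted points outside the image were clipped", oob)
    x = np.clip(x, 0, w - 1)
    y = np.clip(y, 0, h - 1)
    if interpolation == "bilinear":
        vals = _ndi.map_coordinates(dt, np.vstack([y, x]), order=1)
    elif interpolation == "nearest":
        vals = dt[np.rint(y).astype(int), np.rint(x).astype(int)]
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return float(vals.mean() * pixel_spacing), oob


def evaluate_sequence(
    centerlines,
    centerline_images,
    predicted_tp: np.ndarray,
    window_starts,
    W: int,
    pixel_spacing: float,
    truth_tp: np.ndarray | None = None,
    interpolation: str = "nearest",
) -> EvaluationReport:
    """Score a set of multi-horizon forecasts on one sequence.

    Parameters
    ----------
    centerlines : sequence
        Per-frame extracted centerlines (``CenterlinePointSet`` or N x 2
        arrays), indexable by frame; frame ``s + W`` is the last observed
        frame of the window starting at TP row ``s``.
    centerline_images : sequence of 2D bool arrays
        Reference centerline images per frame (the DT is computed on
        these).
    predicted_tp : (K, P, 6) array
        Denormalized TP forecasts for K test windows.
    window_starts : K ints
        TP row index ``s`` of each window; predicted row j of window k
        is the transform of frame ``s + W + j`` onto ``s + W + j + 1``.
    W : int
        Window length in transforms.
    pixel_spacing : float
        mm per pixel for the DT error.
    truth_tp : optional (K, P, 6) array
        Reference TP values aligned with ``predicted_tp``; enables the
        per-parameter MAE block of the report.
    """
    predicted_tp = np.asarray(predicted_tp, dtype=float)
    if predicted_tp.ndim != 3 or predicted_tp.shape[2] != 6:
        raise ValueError("predicted_tp must be (K, P, 6)")
    K, P, _ = predicted_tp.shape
    if len(window_starts) != K:
        raise ValueError("window_starts must align with predicted_tp")

    mae = None
    if truth_tp is not None:
        mae = mae_table(predicted_tp, truth_tp)

    per_frame: list[float] = []
    by_step: list[list[float]] = [[] for _ in range(P)]
    oob_total = 0
    skipped: list[int] = []
    n_frames = len(centerline_images)

    for k, s in enumerate(window_starts):
        base_frame = s + W
        base = centerlines[base_frame]
        base_pts = base.points if hasattr(base, "points") else np.asarray(base)
        cum = np.eye(3)
        for jdx in range(P):
            cum = tp_to_matrix(predicted_tp[k, jdx]) @ cum
            target_frame = base_frame + jdx + 1
            if target_frame >= n_frames or centerline_images[target_frame] is None:
                skipped.append(target_frame)
                continue
            moved = apply_transform(cum, base_pts)
            err, oob = distance_transform_error(
                centerline_images[target_frame], moved, pixel_spacing,
                interpolation=interpolation)
            per_frame.append(err)
            by_step[jdx].append(err)
            oob_total += oob

    mean_dt = float(np.mean(per_frame)) if per_frame else None
    per_step = [float(np.mean(v)) if v else float("nan") for v in by_step]
    if skipped:
        logger.warning("skipped %d horizon frames without centerlines", len(skipped))
    return EvaluationReport(per_parameter_mae=mae, mean_dt_error_mm=mean_dt,
                            per_frame_dt_error=per_frame,
                            per_step_dt_error=per_step,
                            pixel_spacing=pixel_spacing,
                            n_out_of_bounds=oob_total,
                            skipped_frames=skipped)
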