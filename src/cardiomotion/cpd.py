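"""Affine Coherent Point Drift (CPD) registration of centerline point sets.

CPD treats the source point set as the centroids of a Gaussian mixture and
the target set as data drawn from it, plus a uniform outlier component of
weight ``w``.  EM alternates soft correspondence (E-step) with a closed-form
weighted least-squares update of an affine map and the isotropic variance
``sigma^2`` (M-step).  The affine variant is used because every downstream
quantity in this pipeline is the six-entry affine matrix
``(A00, A01, Tx, A10, A11, Ty)``.

Registration direction is fixed as previous frame -> current frame, i.e. the
returned transform pushes frame ``t`` points onto frame ``t+1``, so a
sequence of results reads as motion forward in time.  Pass
``direction="backward"`` to :func:`register_sequence` to invert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .affine import apply_transform
from .segmentation import CenterlinePointSet

__all__ = [
    "CPDConfig",
    "CPDResult",
    "RegistrationError",
    "AffineCPD",
    "cpd_affine",
    "register_sequence",
]

logger = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    """Raised for degenerate inputs or a diverged EM iteration."""


@dataclass(frozen=True)
class CPDConfig:
    """EM hyperparameters.

    w            weight of the uniform outlier component, in [0, 1)
    max_iterations  EM iteration cap
    tolerance    relative change of the negative log-likelihood below
                 which the iteration stops
    anneal_rate  per-iteration floor on the sigma^2 decrease (sigma^2 may
                 shrink by at most this factor each step).  The bounded
                 annealing prevents the variance from collapsing onto a
                 shifted correspondence for uniformly sampled curves,
                 where plain EM locks into a slide-along-the-curve local
                 optimum.  Since the capped value still lies on the
                 descent side of the likelihood in sigma^2, the objective
                 remains non-increasing.
    coarse_to_fine_gate  normalized sigma^2 (units of squared target RMS
                 radius) below which the full affine update is enabled;
                 while the mixture is blurrier than this, only the
                 translation is updated.  With near-uniform
                 responsibilities the unconstrained weighted
                 least-squares affine collapses to a singular squash of
                 the model set, from which EM anneals into reflected or
                 rotated local optima; only the coarsest degrees of
                 freedom are identifiable at high blur.
    """

    w: float = 0.1
    max_iterations: int = 300
    tolerance: float = 1e-8
    anneal_rate: float = 0.9
    coarse_to_fine_gate: float = 0.0625

    def __post_init__(self) -> None:
        if not 0.0 <= self.w < 1.0:
            raise ValueError("outlier weight w must lie in [0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0.0 < self.anneal_rate < 1.0:
            raise ValueError("anneal_rate must lie in (0, 1)")
        if self.coarse_to_fine_gate < 0:
            raise ValueError("coarse_to_fine_gate must be >= 0")


@dataclass
class CPDResult:
    transform: np.ndarray  # 3x3 homogeneous, source -> target
    sigma2_final: float
    n_iterations: int
    converged: bool
    objective: float  # final negative log-likelihood


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, CenterlinePointSet):
        pts = obj.points
    else:
        pts = np.asarray(obj, dtype=float)
    pts = np.atleast_2d(pts)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an N x 2 point array, got shape {pts.shape}")
    return pts.astype(float)


class AffineCPD(BaseEstimator):
    """Affine CPD as a scikit-learn style estimator.

    ``fit(source, target)`` estimates the affine map carrying ``source``
    onto ``target``; fitted attributes are ``transform_`` (3x3), ``sigma2_``,
    ``n_iter_``, ``converged_`` and ``objective_``.

    Parameters
    ----------
    w : float
        Uniform outlier weight in [0, 1).  0 assumes no spurious points.
    max_iterations : int
        EM iteration cap.
    tolerance : float
        Stop when the relative negative log-likelihood change drops below
        this value.
    """

    def __init__(self, w: float = 0.1, max_iterations: int = 300,
                 tolerance: float = 1e-8, anneal_rate: float = 0.9,
                 coarse_to_fine_gate: float = 0.0625):
        self.w = w
        self.max_iterations = max_iterations
        self.tolerance = tolerance
        self.anneal_rate = anneal_rate
        self.coarse_to_fine_gate = coarse_to_fine_gate

    def fit(self, source, target):
        cfg = CPDConfig(self.w, self.max_iterations, self.tolerance,
                        self.anneal_rate, self.coarse_to_fine_gate)
        Y = _as_points(source)  # GMM centroids (moving)
        X = _as_points(target)  # data (fixed)
        if len(Y) == 0 or len(X) == 0:
            raise RegistrationError("point sets must be non-empty")
        if len(Y) < 3:
            raise RegistrationError("source needs at least 3 points for an affine fit")
        Yc = Y - Y.mean(axis=0)
        if np.linalg.matrix_rank(Yc, tol=1e-9 * max(1.0, np.abs(Yc).max())) < 2:
            raise RegistrationError("source points are collinear; affine underdetermined")

        M, N, D = len(Y), len(X), 2
        # Work in normalized coordinates (zero mean, unit RMS radius of the
        # target): keeps the Gaussian and uniform-outlier densities on a
        # comparable footing so the outlier class cannot swallow all the
        # probability mass while sigma^2 is still large.
        mu_X0, mu_Y0 = X.mean(axis=0), Y.mean(axis=0)
        scale = float(np.sqrt(((X - mu_X0) ** 2).sum(axis=1).mean()))
        scale = max(scale, 1e-9)
        X = (X - mu_X0) / scale
        Y = (Y - mu_Y0) / scale

        B = np.eye(D)
        t = np.zeros(D)
        sigma2 = cdist(X, Y, "sqeuclidean").sum() / (D * M * N)
        prev_nll = np.inf
        nll = np.inf
        converged = False
        it = 0
        history: list[float] = []

        for it in range(1, cfg.max_iterations + 1):
            d2 = cdist(X, Y @ B.T + t, "sqeuclidean")
            g = np.exp(-d2 / (2.0 * sigma2))  # N x M
            denom = g.sum(axis=1)
            # Uniform outlier component (density 1/N over the data domain).
            c_out = ((2.0 * np.pi * sigma2) ** (D / 2.0)
                     * cfg.w / (1.0 - cfg.w) * M / N) if cfg.w > 0 else 0.0
            denom_full = np.maximum(denom + c_out, np.finfo(float).tiny)
            P = g / denom_full[:, None]  # posterior responsibilities, N x M

            # Negative log-likelihood up to w-dependent constants; the
            # sigma^2-dependent normalization term must be kept for the
            # descent property to hold.
            nll = -np.log(denom_full).sum() + N * D / 2.0 * np.log(sigma2)
            history.append(float(nll))

            Np = P.sum()
            if Np <= 0 or not np.isfinite(Np):
                raise RegistrationError("all correspondences collapsed to outliers")
            Pt1 = P.sum(axis=1)  # N
            P1 = P.sum(axis=0)  # M
            mu_x = (Pt1 @ X) / Np
            mu_y = (P1 @ Y) / Np
            Xh = X - mu_x
            Yh = Y - mu_y
            A = Xh.T @ P @ Yh  # D x D
            fine = sigma2 <= cfg.coarse_to_fine_gate
            if fine:
                G = (Yh * P1[:, None]).T @ Yh
                try:
                    B = A @ np.linalg.inv(G)
                except np.linalg.LinAlgError as exc:
                    raise RegistrationError(
                        "degenerate weighted covariance in M-step") from exc
            t = mu_x - B @ mu_y
            trXPX = float((Pt1 * (Xh ** 2).sum(axis=1)).sum())
            if fine:
                sigma2_ml = (trXPX - float(np.trace(A @ B.T))) / (Np * D)
            else:
                # residual for the fixed (identity) linear part
                trYPY = float((P1 * ((Yh @ B.T) ** 2).sum(axis=1)).sum())
                sigma2_ml = (trXPX - 2.0 * float(np.trace(A @ B.T)) + trYPY) \
                    / (Np * D)
            if not np.isfinite(sigma2_ml):
                raise RegistrationError("sigma^2 became non-finite during EM")
            sigma2_ml = max(sigma2_ml, 1e-10)
            annealing = sigma2_ml < cfg.anneal_rate * sigma2
            sigma2 = max(sigma2_ml, cfg.anneal_rate * sigma2)

            # Stop once the objective has plateaued and the bounded
            # annealing schedule is no longer driving sigma^2 down.
            if (np.isfinite(prev_nll)
                    and abs(prev_nll - nll) < cfg.tolerance * max(abs(prev_nll), 1.0)
                    and not annealing):
                converged = True
                break
            prev_nll = nll

        # Denormalize: the linear part is scale-invariant; the translation
        # folds the normalization shift back in.
        t_full = scale * t + mu_X0 - B @ mu_Y0
        self.transform_ = np.array([[B[0, 0], B[0, 1], t_full[0]],
                                    [B[1, 0], B[1, 1], t_full[1]],
                                    [0.0, 0.0, 1.0]])
        self.sigma2_ = float(sigma2 * scale ** 2)
        self.n_iter_ = it
        self.converged_ = converged
        self.objective_ = float(nll)
        self.objective_history_ = history
        return self

    def transform(self, points) -> np.ndarray:
        """Map points with the fitted affine."""
        return apply_transform(self.transform_, _as_points(points))


def cpd_affine(source, target, cfg: CPDConfig | None = None) -> CPDResult:
    """Functional wrapper over :class:`AffineCPD`."""
    cfg = cfg or CPDConfig()
    est = AffineCPD(w=cfg.w, max_iterations=cfg.max_iterations,
                    tolerance=cfg.tolerance, anneal_rate=cfg.anneal_rate,
                    coarse_to_fine_gate=cfg.coarse_to_fine_gate).fit(source, target)
    return CPDResult(transform=est.transform_, sigma2_final=est.sigma2_,
                     n_iterations=est.n_iter_, converged=est.converged_,
                     objective=est.objective_)


def register_sequence(centerlines, cfg: CPDConfig | None = None,
                      direction: str = "forward") -> list[np.ndarray]:
    """Register every consecutive centerline pair in a sequence.

    Returns ``len(centerlines) - 1`` affine matrices; element ``t`` maps
    frame ``t`` onto frame ``t+1`` (``direction="forward"``, the default)
    or frame ``t+1`` onto frame ``t`` (``"backward"``).  A failure on any
    pair is re-raised with its frame index.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    if len(centerlines) < 2:
        raise ValueError("need at least 2 frames to register a sequence")
    cfg = cfg or CPDConfig()
    out: list[np.ndarray] = []
    for tdx in range(len(centerlines) - 1):
        src, tgt = centerlines[tdx], centerlines[tdx + 1]
        if direction == "backward":
            src, tgt = tgt, src
        try:
            res = cpd_affine(src, tgt, cfg)
        except (RegistrationError, ValueError) as exc:
            raise RegistrationError(
                f"registration failed for frame pair ({tdx}, {tdx + 1}): {exc}"
            ) from exc
        if not res.converged:
            logger.warning("CPD did not converge for frame pair (%d, %d) "
                           "(%d iterations)", tdx, tdx + 1, res.n_iterations)
        out.append(res.transform)
    return out
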