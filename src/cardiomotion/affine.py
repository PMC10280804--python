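"""2D homogeneous affine algebra shared across the pipeline.

Convention (global to the package): points are ``(x=column, y=row)`` with the
origin at the top-left pixel centre, 0-based.  All affine matrices are 3x3
homogeneous with bottom row ``(0, 0, 1)`` and act on column vectors
``(x, y, 1)^T``.  A frame-to-frame motion transform maps the *previous*
frame's coordinates onto the *current* frame's.

The six free entries of a transform are ordered ``(Tx, Ty, A00, A01, A10,
A11)`` when flattened into a transformation-parameter (TP) vector; this
ordering is used by every CSV schema and by the forecasting model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TP_COLUMNS",
    "AffineParams",
    "compose_affine",
    "decompose_entries",
    "matrix_to_tp",
    "tp_to_matrix",
    "apply_transform",
    "identity",
    "invert",
    "is_valid_affine",
    "shift_origin",
]

#: Column order of a TP vector / CSV row.
TP_COLUMNS = ("Tx", "Ty", "A00", "A01", "A10", "A11")


@dataclass(frozen=True)
class AffineParams:
    """Geometric parameterization of a 2D affine transform.

    Rotation by ``theta`` (radians) and anisotropic scaling ``(sx, sy)``
    about the centre ``(cx, cy)`` (pixels), followed by a translation
    ``(x, y)`` (pixels).

    ``sx`` and ``sy`` must be positive.
    """

    sx: float = 1.0
    sy: float = 1.0
    theta: float = 0.0
    cx: float = 0.0
    cy: float = 0.0
    x: float = 0.0
    y: float = 0.0

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError(f"scales must be positive, got sx={self.sx}, sy={self.sy}")


def compose_affine(p: AffineParams) -> np.ndarray:
    """Build the 3x3 homogeneous matrix from geometric parameters.

    Closed form::

        A00 = sx*cos(th)   A01 = sy*sin(th)
        A10 = -sx*sin(th)  A11 = sy*cos(th)
        Tx  = x - cx*sx*cos(th) - cy*sy*sin(th)
        Ty  = y + cx*sx*sin(th) - cy*sy*cos(th)

    Note the translation entries are expressed relative to the rotation /
    scaling centre ``(cx, cy)`` so that the centre itself is displaced by
    exactly ``(x - cx, y - cy)``.
    """
    ct, st = np.cos(p.theta), np.sin(p.theta)
    a00 = p.sx * ct
    a01 = p.sy * st
    a10 = -p.sx * st
    a11 = p.sy * ct
    tx = p.x - p.cx * p.sx * ct - p.cy * p.sy * st
    ty = p.y + p.cx * p.sx * st - p.cy * p.sy * ct
    return np.array([[a00, a01, tx], [a10, a11, ty], [0.0, 0.0, 1.0]])


def decompose_entries(matrix: np.ndarray) -> dict[str, float]:
    """Return the six free entries of ``matrix`` by name."""
    m = np.asarray(matrix, dtype=float)
    return {
        "A00": m[0, 0], "A01": m[0, 1], "Tx": m[0, 2],
        "A10": m[1, 0], "A11": m[1, 1], "Ty": m[1, 2],
    }


def matrix_to_tp(matrix: np.ndarray) -> np.ndarray:
    """Flatten a 3x3 affine into a TP vector ``(Tx, Ty, A00, A01, A10, A11)``."""
    m = np.asarray(matrix, dtype=float)
    _check_matrix(m)
    return np.array([m[0, 2], m[1, 2], m[0, 0], m[0, 1], m[1, 0], m[1, 1]])


def tp_to_matrix(tp: np.ndarray) -> np.ndarray:
    """Inverse of :func:`matrix_to_tp`."""
    tx, ty, a00, a01, a10, a11 = np.asarray(tp, dtype=float)
    return np.array([[a00, a01, tx], [a10, a11, ty], [0.0, 0.0, 1.0]])


def identity() -> np.ndarray:
    return np.eye(3)


def invert(matrix: np.ndarray) -> np.ndarray:
    """Inverse affine; the bottom row is restored exactly."""
    inv = np.linalg.inv(np.asarray(matrix, dtype=float))
    inv[2] = (0.0, 0.0, 1.0)
    return inv


def is_valid_affine(matrix: np.ndarray, *, det_tol: float = 1e-8) -> bool:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3) or not np.all(np.isfinite(m)):
        return False
    if not np.array_equal(m[2], (0.0, 0.0, 1.0)):
        return False
    return abs(np.linalg.det(m[:2, :2])) > det_tol


def _check_matrix(m: np.ndarray) -> None:
    if m.shape != (3, 3):
        raise ValueError(f"expected a 3x3 homogeneous matrix, got shape {m.shape}")
    if not np.array_equal(m[2], (0.0, 0.0, 1.0)):
        raise ValueError(f"bottom row must be (0, 0, 1), got {m[2]}")


def shift_origin(matrix: np.ndarray, origin) -> np.ndarray:
    """Re-express an affine about a new coordinate origin.

    For points measured relative to ``origin`` (p' = p - origin) the same
    motion is ``T' = S^-1 T S`` with ``S`` the translation by ``origin``:
    the linear part is unchanged and ``t' = A @ origin + t - origin``.
    Apply with the negated origin to undo.

    Re-basing the translation onto the image or structure centre
    decorrelates it from the linear entries: about a remote origin, tiny
    rotation/scale perturbations masquerade as large translations, which
    makes the raw (Tx, Ty) ill-conditioned as a learning target.
    """
    m = np.asarray(matrix, dtype=float)
    _check_matrix(m)
    o = np.asarray(origin, dtype=float)
    out = m.copy()
    out[:2, 2] = m[:2, :2] @ o + m[:2, 2] - o
    return out


def apply_transform(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a homogeneous affine to an ``N x 2`` array of ``(x, y)`` points."""
    m = np.asarray(matrix, dtype=float)
    _check_matrix(m)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must be N x 2, got shape {pts.shape}")
    return pts @ m[:2, :2].T + m[:2, 2]
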