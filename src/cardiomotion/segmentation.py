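"""Vessel segmentation and centerline extraction.

The tracking signal is the vessel centerline: each frame is filtered with
the multiscale Frangi vesselness measure (Hessian-eigenvalue tubularity),
thresholded relative to its maximum response, cleaned of small connected
components, and morphologically thinned to a one-pixel-wide skeleton whose
foreground pixels form the centerline point set.

The scale schedule defaults to sigma in [1, 6] pixels with a 0.1 step; the
remaining parameters (beta = 0.5, structureness constant c = half the
maximum Hessian norm per scale) are the standard Frangi choices and are all
overridable per sequence, since contrast and vessel calibre vary between
acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters as _skfilters
from skimage import measure as _skmeasure
from skimage import morphology as _skmorph
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FrangiConfig",
    "SegmentationConfig",
    "CenterlinePointSet",
    "SegmentationError",
    "frangi_vesselness",
    "segment",
    "extract_centerline",
    "FrangiSegmenter",
]


class SegmentationError(RuntimeError):
    """Raised when a frame yields no usable vessel mask."""


@dataclass(frozen=True)
class FrangiConfig:
    """Multiscale Frangi filter configuration (all lengths in pixels)."""

    sigma_min: float = 1.0
    sigma_max: float = 6.0
    sigma_step: float = 0.1
    beta: float = 0.5
    c: float | None = None  # None -> half of max Hessian norm, per scale
    bright_on_dark: bool = True

    def __post_init__(self) -> None:
        if self.sigma_min > self.sigma_max:
            raise ValueError("sigma_min must not exceed sigma_max")
        if self.sigma_step <= 0:
            raise ValueError("sigma_step must be positive")

    @property
    def sigmas(self) -> np.ndarray:
        return np.arange(self.sigma_min, self.sigma_max + 1e-9, self.sigma_step)


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholding and component cleanup after the vesselness filter."""

    vesselness_threshold: float = 0.02  # fraction of max response
    min_component_size: int = 64  # pixels, 8-connected

    def __post_init__(self) -> None:
        if not 0.0 < self.vesselness_threshold < 1.0:
            raise ValueError("vesselness_threshold must be in (0, 1)")
        if self.min_component_size < 1:
            raise ValueError("min_component_size must be >= 1")


@dataclass
class CenterlinePointSet:
    """One frame's skeletonized centerline.

    ``points`` is the N x 2 array of (x, y) pixel coordinates of the
    foreground pixels of ``binary_image`` in row-major order.
    """

    points: np.ndarray
    binary_image: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.points)


def frangi_vesselness(frame: np.ndarray, cfg: FrangiConfig | None = None) -> np.ndarray:
    """Per-pixel maximum Frangi vesselness over the configured scales.

    Response lies in [0, 1]; zero wherever the second Hessian eigenvalue
    has the wrong sign for the configured polarity.
    """
    cfg = cfg or FrangiConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2D frame, got ndim={frame.ndim}")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    return _skfilters.frangi(
        frame,
        sigmas=cfg.sigmas,
        beta=cfg.beta,
        gamma=cfg.c,
        black_ridges=not cfg.bright_on_dark,
    )


def segment(response: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Threshold a vesselness map and drop small 8-connected components."""
    cfg = cfg or SegmentationConfig()
    response = np.asarray(response, dtype=float)
    peak = response.max()
    if peak <= 0:
        raise SegmentationError("vesselness response is identically zero")
    mask = response >= cfg.vesselness_threshold * peak
    labels = _skmeasure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= cfg.min_component_size)
    keep = keep[keep != 0]  # label 0 is background
    mask = np.isin(labels, keep)
    if not mask.any():
        raise SegmentationError(
            f"no component of >= {cfg.min_component_size} px survived thresholding"
        )
    return mask


def extract_centerline(mask: np.ndarray) -> CenterlinePointSet:
    """Thin a binary mask to a 1-px topology-preserving skeleton."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("cannot skeletonize an empty mask")
    skel = _skmorph.skeletonize(mask)
    rc = np.argwhere(skel)  # row-major (row, col)
    points = rc[:, ::-1].astype(float)  # -> (x, y)
    return CenterlinePointSet(points=points, binary_image=skel)


class FrangiSegmenter(BaseEstimator, TransformerMixin):
    """Frame -> centerline transformer (vesselness, threshold, skeleton).

    A stateless scikit-learn style transformer; ``fit`` only validates the
    configuration so the segmenter can sit inside a ``Pipeline``.

    Parameters
    ----------
    sigma_min, sigma_max, sigma_step : float
        Frangi scale schedule, pixels.
    beta : float
        Blob-vs-line sensitivity of the vesselness measure.
    c : float or None
        Structureness constant; ``None`` uses half the maximum Hessian
        norm at each scale.
    bright_on_dark : bool
        Polarity of the vessels; set False for raw (dark-vessel) X-ray.
    vesselness_threshold : float
        Mask threshold as a fraction of the maximum response.
    min_component_size : int
        Minimum surviving 8-connected component area, pixels.
    """

    def __init__(self, sigma_min: float = 1.0, sigma_max: float = 6.0,
                 sigma_step: float = 0.1, beta: float = 0.5,
                 c: float | None = None, bright_on_dark: bool = True,
                 vesselness_threshold: float = 0.02,
                 min_component_size: int = 64):
        self.sigma_min = sigma_min
        self.sigma_max = sigma_max
        self.sigma_step = sigma_step
        self.beta = beta
        self.c = c
        self.bright_on_dark = bright_on_dark
        self.vesselness_threshold = vesselness_threshold
        self.min_component_size = min_component_size

    def _configs(self) -> tuple[FrangiConfig, SegmentationConfig]:
        return (
            FrangiConfig(self.sigma_min, self.sigma_max, self.sigma_step,
                         self.beta, self.c, self.bright_on_dark),
            SegmentationConfig(self.vesselness_threshold, self.min_component_size),
        )

    def fit(self, X=None, y=None):
        self.frangi_config_, self.segmentation_config_ = self._configs()
        return self

    def transform_frame(self, frame: np.ndarray) -> CenterlinePointSet:
        """Full per-frame chain: vesselness -> mask -> skeleton."""
        fcfg, scfg = self._configs()
        response = frangi_vesselness(frame, fcfg)
        mask = segment(response, scfg)
        return extract_centerline(mask)

    def transform(self, X) -> list[CenterlinePointSet]:
        """Apply :meth:`transform_frame` to a (T, H, W) stack or frame list."""
        return [self.transform_frame(f) for f in X]
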