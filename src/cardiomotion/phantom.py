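"""Synthetic 2D vessel phantom with known cardio-respiratory affine motion.

Real interventional angiography sequences (and the computational phantoms
used to prototype motion models) are not redistributable, so this module
generates a surrogate: a smooth branching 2D vessel tree rendered as a
bright-on-dark grayscale sequence, animated by the superposition of two
periodic affine motions — a fast "cardiac" component (period about 1 s) and
a slow "respiratory" component (period about 5 s) — optionally disturbed by
aperiodic translation bursts that mimic unexpected patient movement.

Every sequence carries its exact per-frame affine ground truth, which makes
all downstream stages (segmentation, registration, forecasting, scoring)
testable end to end.

Coordinate convention: points are ``(x=column, y=row)``; matrices act on
``(x, y, 1)^T`` (see :mod:`cardiomotion.affine`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import interpolate as _interp
from scipy.ndimage import gaussian_filter

from .affine import AffineParams, apply_transform, compose_affine, invert

__all__ = [
    "VesselTree",
    "MotionAmplitude",
    "MotionBurst",
    "MotionSpec",
    "FrameSequence",
    "GroundTruthSequence",
    "generate_vessel_tree",
    "motion_at",
    "render_sequence",
]


@dataclass
class VesselTree:
    """A connected branching tree of smooth 2D polylines.

    ``segments[0]`` is the main branch; every later segment starts on a
    point of an earlier one, so the tree is connected by construction.
    """

    segments: list[np.ndarray]
    vessel_width: float
    canvas_size: tuple[int, int]

    @property
    def all_points(self) -> np.ndarray:
        return np.vstack(self.segments)

    @property
    def centroid(self) -> np.ndarray:
        return self.all_points.mean(axis=0)


@dataclass(frozen=True)
class MotionAmplitude:
    """Peak excursion of one periodic motion component.

    translation_mm   peak displacement of the tree centroid along the
                     component's direction (millimetres)
    rotation_deg     peak rotation about the centroid (degrees)
    scale_fraction   peak isotropic scale deviation from 1 (e.g. 0.02)
    direction        unit 2D direction of the translation, (x, y)
    """

    translation_mm: float = 0.0
    rotation_deg: float = 0.0
    scale_fraction: float = 0.0
    direction: tuple[float, float] = (1.0, 0.0)


@dataclass(frozen=True)
class MotionBurst:
    """Aperiodic extra translation emulating patient movement."""

    onset_frame: int
    duration_frames: int
    magnitude_mm: float
    direction: tuple[float, float] = (1.0, 0.0)


# Cardiac motion of coronary trees is roughly isotropic in the image plane;
# respiratory motion is dominated by the cranio-caudal (image y) axis.
_CARDIAC_DIR = (0.8, 0.6)
_RESP_DIR = (0.242535625, 0.9701425)


@dataclass
class MotionSpec:
    """Full description of a simulated motion pattern.

    Periods are in seconds, the frame rate in frames/second.  Default
    periods follow the normal resting physiology the simulation emulates:
    a 1 s heartbeat and a 5 s breathing cycle.  ``mode`` activates either
    or both components.  The ``center`` of rotation/scaling defaults to
    the vessel-tree centroid (filled in by :func:`render_sequence`).
    """

    cardiac_period: float = 1.0
    respiratory_period: float = 5.0
    cardiac_amplitude: MotionAmplitude = field(
        default_factory=lambda: MotionAmplitude(5.0, 2.0, 0.02, _CARDIAC_DIR)
    )
    respiratory_amplitude: MotionAmplitude = field(
        default_factory=lambda: MotionAmplitude(10.0, 1.0, 0.01, _RESP_DIR)
    )
    mode: str = "both"  # {"cardiac_only", "respiratory_only", "both"}
    irregularity: list[MotionBurst] = field(default_factory=list)
    frame_rate: float = 7.5
    n_frames: int = 75
    pixel_spacing: float = 0.35  # mm / pixel
    rng_seed: int = 0
    cardiac_waveform: str = "sin"  # "sin" or "sin2" (sharper systolic peak)
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)  # linear drift
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.cardiac_period <= 0 or self.respiratory_period <= 0:
            raise ValueError("motion periods must be positive")
        if self.n_frames < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if self.mode not in ("cardiac_only", "respiratory_only", "both"):
            raise ValueError(f"unknown motion mode {self.mode!r}")
        if self.cardiac_waveform not in ("sin", "sin2"):
            raise ValueError(f"unknown cardiac waveform {self.cardiac_waveform!r}")
        if self.frame_rate <= 0 or self.pixel_spacing <= 0:
            raise ValueError("frame_rate and pixel_spacing must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FrameSequence:
    """Ordered grayscale image stack with physical metadata."""

    frames: np.ndarray  # (T, H, W) float in [0, 1]
    pixel_spacing: float  # mm / pixel
    frame_interval: float  # seconds between frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class GroundTruthSequence:
    """Rendered frames plus the exact motion that produced them.

    ``true_transforms[t]`` maps frame ``t`` coordinates onto frame ``t+1``
    (length ``n_frames - 1``).  ``true_points[t]`` are the sub-pixel
    centerline polyline samples of frame ``t``; ``true_centerline_images``
    are their rasterized (rounded) binary counterparts.
    """

    frames: FrameSequence
    true_transforms: list[np.ndarray]
    true_points: list[np.ndarray]
    true_centerline_images: list[np.ndarray]
    spec: MotionSpec
    tree: VesselTree


def _smooth_polyline(ctrl: np.ndarray, n_samples: int) -> np.ndarray:
    """Cubic B-spline through control points, densely sampled."""
    k = min(3, len(ctrl) - 1)
    tck, _ = _interp.splprep([ctrl[:, 0], ctrl[:, 1]], s=0, k=k)
    u = np.linspace(0.0, 1.0, n_samples)
    x, y = _interp.splev(u, tck)
    return np.column_stack([x, y])


def generate_vessel_tree(
    rng_seed: int,
    n_branches: int = 5,
    canvas_size: tuple[int, int] = (256, 256),
    vessel_width: float = 3.0,
    margin_fraction: float = 0.30,
) -> VesselTree:
    """Generate a random connected branching vessel tree.

    The tree is confined to the central box of the canvas, leaving
    ``margin_fraction`` of each dimension free on every side so that the
    subsequent motion cannot push it off the image.  Deterministic for a
    given ``rng_seed``.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    h, w = canvas_size
    my, mx = h * margin_fraction, w * margin_fraction
    box = (mx, my, w - 1 - mx, h - 1 - my)  # x0, y0, x1, y1
    if box[2] - box[0] < 24 or box[3] - box[1] < 24:
        raise ValueError(
            f"canvas {canvas_size} too small to place a vessel tree with "
            f"margin_fraction={margin_fraction}"
        )
    rng = np.random.default_rng(rng_seed)
    x0, y0, x1, y1 = box
    span = min(x1 - x0, y1 - y0)

    # Main branch: waypoints drifting across the safe box with jitter.
    n_ctrl = 5
    tx = np.linspace(x0 + 0.08 * (x1 - x0), x1 - 0.08 * (x1 - x0), n_ctrl)
    ty = np.linspace(y0 + 0.15 * (y1 - y0), y1 - 0.15 * (y1 - y0), n_ctrl)
    jitter = 0.10 * span
    ctrl = np.column_stack([
        tx + rng.uniform(-jitter, jitter, n_ctrl),
        ty + rng.uniform(-jitter, jitter, n_ctrl),
    ])
    segments = [_smooth_polyline(ctrl, 200)]

    for _ in range(n_branches - 1):
        parent = segments[rng.integers(0, len(segments))]
        i = int(rng.uniform(0.2, 0.8) * (len(parent) - 1))
        start = parent[i]
        tangent = parent[min(i + 1, len(parent) - 1)] - parent[max(i - 1, 0)]
        tangent = tangent / (np.linalg.norm(tangent) + 1e-12)
        ang = np.deg2rad(rng.uniform(30, 70)) * rng.choice([-1.0, 1.0])
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        direction = tangent @ rot.T
        length = rng.uniform(0.25, 0.5) * span
        n_c = 4
        dists = np.linspace(0, length, n_c)
        perp = np.array([-direction[1], direction[0]])
        wiggle = rng.uniform(-0.12, 0.12, n_c) * length
        wiggle[0] = 0.0
        ctrl = start + np.outer(dists, direction) + np.outer(wiggle, perp)
        ctrl[:, 0] = np.clip(ctrl[:, 0], x0, x1)
        ctrl[:, 1] = np.clip(ctrl[:, 1], y0, y1)
        segments.append(_smooth_polyline(ctrl, max(40, int(length * 1.5))))

    # Splines can overshoot clipped control points slightly; shrink the whole
    # tree about its centroid until it fits the safe box.
    pts = np.vstack(segments)
    c = pts.mean(axis=0)
    half_x = max(c[0] - x0, x1 - c[0])
    half_y = max(c[1] - y0, y1 - c[1])
    ext_x = max(np.max(pts[:, 0] - c[0]), np.max(c[0] - pts[:, 0]))
    ext_y = max(np.max(pts[:, 1] - c[1]), np.max(c[1] - pts[:, 1]))
    scale = min(1.0, 0.999 * half_x / max(ext_x, 1e-9), 0.999 * half_y / max(ext_y, 1e-9))
    if scale < 1.0:
        segments = [c + scale * (s - c) for s in segments]

    return VesselTree(segments=segments, vessel_width=float(vessel_width),
                      canvas_size=canvas_size)


def _waveform(phase: float, kind: str) -> float:
    s = np.sin(2.0 * np.pi * phase)
    if kind == "sin2":
        return float(np.sign(s) * s * s)
    return float(s)


def _component_matrix(t_sec: float, period: float, amp: MotionAmplitude,
                      center: tuple[float, float], spacing: float,
                      waveform: str) -> np.ndarray:
    w = _waveform(t_sec / period, waveform)
    amp_px = amp.translation_mm / spacing
    d = np.asarray(amp.direction, dtype=float)
    d = d / (np.linalg.norm(d) + 1e-12)
    dx, dy = amp_px * w * d
    theta = np.deg2rad(amp.rotation_deg) * w
    s = 1.0 + amp.scale_fraction * w
    cx, cy = center
    return compose_affine(AffineParams(sx=s, sy=s, theta=theta, cx=cx, cy=cy,
                                       x=cx + dx, y=cy + dy))


def motion_at(t: int, spec: MotionSpec,
              center: tuple[float, float] | None = None) -> np.ndarray:
    """Absolute affine transform mapping the frame-0 tree to frame ``t``.

    The transform is the composition ``respiratory @ cardiac`` (cardiac
    applied first) of two sinusoidally varying similarity transforms about
    ``center``, plus any active irregularity bursts as extra translation.
    The two components are deliberately *not* phase-locked: their periods
    are independent, so the combined motion is only periodic over the least
    common multiple of the two periods.
    """
    if not 0 <= t < spec.n_frames:
        raise ValueError(f"frame index {t} outside [0, {spec.n_frames})")
    c = center if center is not None else (spec.center or (0.0, 0.0))
    t_sec = t / spec.frame_rate

    m = np.eye(3)
    if spec.mode in ("cardiac_only", "both"):
        m = _component_matrix(t_sec, spec.cardiac_period, spec.cardiac_amplitude,
                              c, spec.pixel_spacing, spec.cardiac_waveform) @ m
    if spec.mode in ("respiratory_only", "both"):
        m = _component_matrix(t_sec, spec.respiratory_period,
                              spec.respiratory_amplitude, c,
                              spec.pixel_spacing, "sin") @ m

    if spec.drift_px_per_frame != (0.0, 0.0):
        shift = np.eye(3)
        shift[:2, 2] = (t * spec.drift_px_per_frame[0],
                        t * spec.drift_px_per_frame[1])
        m = shift @ m

    for burst in spec.irregularity:
        u = (t - burst.onset_frame) / max(burst.duration_frames, 1)
        if 0.0 < u < 1.0:
            bump = np.sin(np.pi * u) ** 2 * burst.magnitude_mm / spec.pixel_spacing
            d = np.asarray(burst.direction, dtype=float)
            d = d / (np.linalg.norm(d) + 1e-12)
            shift = np.eye(3)
            shift[:2, 2] = bump * d
            m = shift @ m
    return m


def _splat(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear accumulation of sub-pixel points onto a float canvas."""
    h, w = shape
    img = np.zeros((h, w))
    x, y = points[:, 0], points[:, 1]
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx, fy = x - x0, y - y0
    for ddy, ddx, wgt in ((0, 0, (1 - fx) * (1 - fy)), (0, 1, fx * (1 - fy)),
                          (1, 0, (1 - fx) * fy), (1, 1, fx * fy)):
        xs, ys = x0 + ddx, y0 + ddy
        ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        np.add.at(img, (ys[ok], xs[ok]), wgt[ok])
    return img


def _resample_arclength(seg: np.ndarray, step: float = 0.5) -> np.ndarray:
    """Resample a polyline to uniform arc-length spacing ``step`` pixels."""
    d = np.linalg.norm(np.diff(seg, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    if s[-1] < step:
        return seg
    n = max(int(s[-1] / step) + 1, 2)
    si = np.linspace(0.0, s[-1], n)
    x = np.interp(si, s, seg[:, 0])
    y = np.interp(si, s, seg[:, 1])
    return np.column_stack([x, y])


def render_sequence(
    tree: VesselTree,
    spec: MotionSpec,
    noise_sd: float = 0.01,
    background: str = "flat",
) -> GroundTruthSequence:
    """Render the moving tree into a grayscale sequence with ground truth.

    Each frame rasterizes the tree transformed by :func:`motion_at` with a
    Gaussian intensity profile of the tree's ``vessel_width``, adds the
    chosen background and i.i.d. Gaussian noise.  Per-step relative
    transforms ``motion_at(t+1) @ motion_at(t)^-1`` are stored as ground
    truth, so composing them from frame 0 recovers the absolute motion.
    """
    if background not in ("flat", "textured"):
        raise ValueError(f"unknown background {background!r}")
    h, w = tree.canvas_size
    center = tuple(tree.centroid)
    dense = np.vstack([_resample_arclength(s) for s in tree.segments])

    abs_transforms = [motion_at(t, spec, center) for t in range(spec.n_frames)]
    rng = np.random.default_rng(spec.rng_seed)

    if background == "textured":
        bg = gaussian_filter(rng.standard_normal((h, w)), sigma=18)
        bg = 0.12 * (bg - bg.min()) / (np.ptp(bg) + 1e-12)
    else:
        bg = np.full((h, w), 0.05)

    frames = np.empty((spec.n_frames, h, w), dtype=np.float32)
    true_points: list[np.ndarray] = []
    true_imgs: list[np.ndarray] = []
    sigma = max(tree.vessel_width / 2.0, 0.5)

    for t, m in enumerate(abs_transforms):
        pts = apply_transform(m, dense)
        if (pts[:, 0].min() < 0 or pts[:, 0].max() > w - 1
                or pts[:, 1].min() < 0 or pts[:, 1].max() > h - 1):
            raise ValueError(
                f"transformed vessel tree leaves the canvas at frame {t}; "
                "increase canvas size or reduce motion amplitude"
            )
        raster = gaussian_filter(_splat(pts, (h, w)), sigma=sigma)
        raster = raster / (raster.max() + 1e-12)
        img = bg + 0.85 * raster
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=(h, w))
        frames[t] = np.clip(img, 0.0, 1.0)

        true_points.append(pts)
        ci = np.zeros((h, w), dtype=bool)
        xs = np.clip(np.rint(pts[:, 0]).astype(int), 0, w - 1)
        ys = np.clip(np.rint(pts[:, 1]).astype(int), 0, h - 1)
        ci[ys, xs] = True
        true_imgs.append(ci)

    rel = [abs_transforms[t + 1] @ invert(abs_transforms[t])
           for t in range(spec.n_frames - 1)]

    seq = FrameSequence(frames=frames, pixel_spacing=spec.pixel_spacing,
                        frame_interval=1.0 / spec.frame_rate)
    return GroundTruthSequence(frames=seq, true_transforms=rel,
                               true_points=true_points,
                               true_centerline_images=true_imgs,
                               spec=spec, tree=tree)
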