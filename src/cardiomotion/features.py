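"""Transformation-parameter (TP) series and supervised windowing.

A sequence of frame-to-frame affine transforms is flattened into a T x 6
array of TP vectors ordered ``(Tx, Ty, A00, A01, A10, A11)``.  Because the
six parameters live on very different scales (translations in pixels versus
linear-part entries near 1 or 0), each column is normalized by its maximum
absolute value before being fed to the forecaster, and denormalized after
prediction.  Normalization factors are computed from training rows only so
that no information from the held-out tail of the sequence leaks into the
inputs.

Sliding stride-1 windows of W past TP vectors paired with the next P
vectors form the supervised dataset; the chronological 80/20 split keeps
all test windows strictly after the training windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .affine import matrix_to_tp, tp_to_matrix

__all__ = [
    "TPSeries",
    "WindowConfig",
    "WindowedDataset",
    "build_tp_series",
    "normalize_tp",
    "denormalize_tp",
    "make_windows",
    "chronological_split",
]


@dataclass
class TPSeries:
    """Time-ordered T x 6 TP array with its normalization state."""

    values: np.ndarray  # T x 6
    norm_factors: np.ndarray | None = None  # 6 per-column scalars
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError(f"TP series must be T x 6, got {self.values.shape}")

    @property
    def n_transforms(self) -> int:
        return self.values.shape[0]

    def to_matrices(self) -> list[np.ndarray]:
        if self.normalized:
            raise ValueError("denormalize before rebuilding matrices")
        return [tp_to_matrix(row) for row in self.values]


@dataclass(frozen=True)
class WindowConfig:
    """W past transforms in, P future transforms out, time-ordered split."""

    W: int = 15
    P: int = 5
    train_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.W < 1 or self.P < 1:
            raise ValueError("W and P must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class WindowedDataset:
    inputs: np.ndarray  # M x W x 6
    targets: np.ndarray  # M x P x 6
    index_map: np.ndarray  # M window start rows

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]


def build_tp_series(transforms) -> TPSeries:
    """Flatten 3x3 affine matrices into an unnormalized TP series."""
    if len(transforms) < 1:
        raise ValueError("need at least one transform")
    return TPSeries(values=np.array([matrix_to_tp(m) for m in transforms]))


def normalize_tp(series: TPSeries, factors: np.ndarray | None = None,
                 n_train_rows: int | None = None) -> TPSeries:
    """Divide each column by its per-parameter normalization factor.

    When ``factors`` is not given, factor_j is the maximum absolute value
    of column j over the first ``n_train_rows`` rows (all rows when None);
    identically-zero columns keep factor 1 so normalization stays
    invertible.
    """
    if series.normalized:
        raise ValueError("series is already normalized")
    v = series.values
    if not np.all(np.isfinite(v)):
        raise ValueError("TP series contains non-finite values")
    if factors is None:
        rows = v if n_train_rows is None else v[:n_train_rows]
        if rows.shape[0] < 1:
            raise ValueError("n_train_rows leaves no rows to compute factors from")
        factors = np.abs(rows).max(axis=0)
        factors = np.where(factors > 0, factors, 1.0)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (6,):
        raise ValueError("factors must be 6 per-column scalars")
    if np.any(factors <= 0):
        raise ValueError("normalization factors must be positive")
    return TPSeries(values=v / factors, norm_factors=factors, normalized=True)


def denormalize_tp(series: TPSeries) -> TPSeries:
    """Invert :func:`normalize_tp` using the stored factors."""
    if not series.normalized:
        raise ValueError("series is not normalized")
    if series.norm_factors is None:
        raise ValueError("series carries no normalization factors")
    return TPSeries(values=series.values * series.norm_factors,
                    norm_factors=series.norm_factors, normalized=False)


def make_windows(series: TPSeries, cfg: WindowConfig | None = None) -> WindowedDataset:
    """All maximal-overlap (stride 1) windows, chronological order.

    Sample i covers input rows [s, s+W) and target rows [s+W, s+W+P) with
    s = i, giving M = T - W - P + 1 samples.
    """
    cfg = cfg or WindowConfig()
    T = series.n_transforms
    if T < cfg.W + cfg.P:
        raise ValueError(
            f"series too short to window: T={T} < W+P={cfg.W + cfg.P}"
        )
    M = T - cfg.W - cfg.P + 1
    v = series.values
    inputs = np.stack([v[s:s + cfg.W] for s in range(M)])
    targets = np.stack([v[s + cfg.W:s + cfg.W + cfg.P] for s in range(M)])
    return WindowedDataset(inputs=inputs, targets=targets,
                           index_map=np.arange(M))


def chronological_split(ds: WindowedDataset,
                        train_fraction: float = 0.8) -> tuple[WindowedDataset, WindowedDataset]:
    """Time-ordered holdout: first floor(f*M) windows train, rest test."""
    M = ds.n_samples
    if M < 2:
        raise ValueError("need at least 2 windows to split")
    n_train = int(np.floor(train_fraction * M))
    if n_train < 1 or n_train >= M:
        raise ValueError(
            f"train_fraction={train_fraction} yields an empty partition for M={M}"
        )
    train = WindowedDataset(ds.inputs[:n_train], ds.targets[:n_train],
                            ds.index_map[:n_train])
    test = WindowedDataset(ds.inputs[n_train:], ds.targets[n_train:],
                           ds.index_map[n_train:])
    return train, test


def training_row_count(T: int, cfg: WindowConfig) -> int:
    """Last TP row index (exclusive) touched by any training window.

    Used to restrict normalization factors to rows the training windows
    can see, so factors are invariant to the held-out tail.
    """
    M = T - cfg.W - cfg.P + 1
    if M < 2:
        raise ValueError("series too short to split")
    n_train = int(np.floor(cfg.train_fraction * M))
    return (n_train - 1) + cfg.W + cfg.P
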