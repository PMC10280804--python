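"""File formats shared by the pipeline stages.

All transform-series files (simulator ground truth, registration output,
predictions) use one CSV schema with header ``frame,A00,A01,Tx,A10,A11,Ty``
so that ground truth and recovered motion are directly diffable.  Frames
are written as multi-page TIFF (16-bit) or a numbered PNG directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .affine import decompose_entries
from .phantom import FrameSequence
from .segmentation import CenterlinePointSet

__all__ = [
    "TRANSFORM_CSV_COLUMNS",
    "save_transforms_csv",
    "load_transforms_csv",
    "save_frames",
    "load_frames",
    "save_centerlines_csv",
    "load_centerlines_csv",
    "save_json",
]

TRANSFORM_CSV_COLUMNS = ("frame", "A00", "A01", "Tx", "A10", "A11", "Ty")


def save_transforms_csv(transforms, path) -> None:
    rows = []
    for t, m in enumerate(transforms):
        e = decompose_entries(m)
        rows.append({"frame": t, **{k: e[k] for k in TRANSFORM_CSV_COLUMNS[1:]}})
    pd.DataFrame(rows, columns=list(TRANSFORM_CSV_COLUMNS)).to_csv(path, index=False)


def load_transforms_csv(path) -> list[np.ndarray]:
    """Read a transform-series CSV back into 3x3 matrices (frame order)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed transform CSV {path}: {exc}") from exc
    missing = set(TRANSFORM_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[~np.isfinite(df[list(TRANSFORM_CSV_COLUMNS[1:])]).all(axis=1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: non-finite values at line {bad.index[0] + 2}")
    df = df.sort_values("frame")
    return [np.array([[r.A00, r.A01, r.Tx], [r.A10, r.A11, r.Ty], [0.0, 0.0, 1.0]])
            for r in df.itertuples()]


def save_frames(seq: FrameSequence, path) -> None:
    """Write frames as multi-page 16-bit TIFF (path ending .tif/.tiff) or
    a directory of numbered PNGs."""
    path = Path(path)
    stack = np.clip(seq.frames, 0.0, 1.0)
    u16 = (stack * 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, u16, metadata={
            "pixel_spacing_mm": seq.pixel_spacing,
            "frame_interval_s": seq.frame_interval,
        })
    else:
        path.mkdir(parents=True, exist_ok=True)
        for t, frame in enumerate(u16):
            iio.imwrite(path / f"frame_{t:04d}.png", frame)
        save_json({"pixel_spacing_mm": seq.pixel_spacing,
                   "frame_interval_s": seq.frame_interval},
                  path / "metadata.json")


def load_frames(path, pixel_spacing: float | None = None,
                frame_interval: float | None = None) -> FrameSequence:
    """Load a multi-page TIFF or a directory of PNG/TIFF frames.

    ``pixel_spacing`` (mm/px) must come from the file metadata or be given
    explicitly — millimetre-denominated outputs are meaningless without it.
    """
    path = Path(path)
    meta: dict = {}
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise ValueError(f"no image frames found in {path}")
        stack = np.stack([iio.imread(p) for p in files])
        meta_path = path / "metadata.json"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
    else:
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            if tf.shaped_metadata:
                meta = dict(tf.shaped_metadata[0])
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a grayscale stack, got shape {stack.shape}")
    stack = stack.astype(np.float32)
    if stack.max() > 1.0:
        stack /= float(np.iinfo(np.uint16).max if stack.max() > 255 else 255)
    spacing = pixel_spacing if pixel_spacing is not None else meta.get("pixel_spacing_mm")
    if spacing is None:
        raise ValueError(
            "pixel spacing (mm/pixel) not found in metadata; pass pixel_spacing="
        )
    interval = frame_interval if frame_interval is not None \
        else meta.get("frame_interval_s", 1.0 / 7.5)
    return FrameSequence(frames=stack, pixel_spacing=float(spacing),
                         frame_interval=float(interval))


def save_centerlines_csv(centerlines, path) -> None:
    rows = []
    for t, cl in enumerate(centerlines):
        pts = cl.points if isinstance(cl, CenterlinePointSet) else np.asarray(cl)
        for x, y in pts:
            rows.append({"frame": t, "x": x, "y": y})
    pd.DataFrame(rows, columns=["frame", "x", "y"]).to_csv(path, index=False)


def load_centerlines_csv(path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    for col in ("frame", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [g[["x", "y"]].to_numpy(dtype=float)
            for _, g in df.groupby("frame", sort=True)]


def save_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
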