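"""File round-trips for the pipeline's exchange formats.

Images travel as multi-page 8-bit TIFF with a YAML sidecar holding the frame
rate and pixel scale; 1-D physiological traces as ``time_s,value`` CSV with an
optional YAML truth sidecar; landmark sets as ``frame,point_index,x_px,y_px``
CSV with 0-based indices.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .asm import LandmarkShape, LandmarkTrajectory
from .synthetic import EmgTrace, ForceTrace, ImageSequence

__all__ = [
    "write_image_sequence",
    "read_image_sequence",
    "write_trace",
    "read_trace",
    "write_landmarks",
    "read_landmarks",
]


def write_image_sequence(seq: ImageSequence, path: str | Path) -> None:
    """Write a multi-page TIFF plus a ``<stem>.yaml`` metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, seq.frames, photometric="minisblack")
    meta = {
        "frame_rate_hz": float(seq.frame_rate_hz),
        "mm_per_px_x": float(seq.mm_per_px_x),
        "mm_per_px_y": float(seq.mm_per_px_y),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def read_image_sequence(path: str | Path) -> ImageSequence:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    n = frames.shape[0]
    ts = np.arange(n) / meta["frame_rate_hz"]
    return ImageSequence(frames, meta["frame_rate_hz"], meta["mm_per_px_x"],
                         meta["mm_per_px_y"], ts)


def write_trace(trace: ForceTrace | EmgTrace, path: str | Path) -> None:
    """Write ``time_s,value`` CSV (full float precision)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times, "value": trace.values})
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace(path: str | Path, kind: str = "force") -> ForceTrace | EmgTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace must contain at least two samples")
    fs = 1.0 / np.median(np.diff(t))
    cls = ForceTrace if kind == "force" else EmgTrace
    return cls(df["value"].to_numpy(), float(round(fs, 6)))


def write_landmarks(
    shapes: list[LandmarkShape] | LandmarkTrajectory, path: str | Path
) -> None:
    """Write landmark coordinates as ``frame,point_index,x_px,y_px`` CSV."""
    if isinstance(shapes, LandmarkTrajectory):
        df = shapes.to_dataframe()
    else:
        rows = []
        for s in shapes:
            for j, (x, y) in enumerate(s.points):
                rows.append({"frame": s.frame_index, "point_index": j,
                             "x_px": x, "y_px": y})
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.17g")


def read_landmarks(path: str | Path) -> list[LandmarkShape]:
    df = pd.read_csv(path, float_precision="round_trip")
    shapes = []
    for frame, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("point_index")
        pts = grp[["x_px", "y_px"]].to_numpy()
        shapes.append(LandmarkShape(pts, int(frame)))
    return shapes
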