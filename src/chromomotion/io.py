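"""Reading and writing stacks, tracks and transforms.

Stacks are multi-page TIFF with axis order ``CTZYX``; calibration (voxel
size, frame interval) is taken from the ImageJ-style metadata written by
:func:`write_stack` and can always be overridden by the caller. Tracks
travel as CSV with µm-suffixed columns (``track_id, frame, x_um, y_um,
z_um``), the interchange format between the tracking and motion-analysis
stages.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import TimelapseStack, Trajectory

__all__ = [
    "read_stack",
    "write_stack",
    "write_tracks",
    "read_tracks",
    "write_transforms",
]


def write_stack(stack: TimelapseStack, path) -> None:
    """Write a stack as TIFF with axes CTZYX and calibration metadata."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.ascontiguousarray(stack.data.astype(np.float32)),
        photometric="minisblack",
        metadata={
            "axes": "CTZYX",
            "voxel_size_um": list(stack.voxel_size_um),
            "dt_s": stack.dt_s,
        },
    )


def read_stack(
    path,
    voxel_size_um: tuple[float, float, float] | None = None,
    dt_s: float | None = None,
) -> TimelapseStack:
    """Read a TIFF stack; calibration comes from metadata unless overridden.

    2D or 3D arrays are promoted to the full (C, T, Z, Y, X) layout with a
    warning. Raises when no calibration is available at all.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim == 2:
        warnings.warn("2D image promoted to C=1, T=1, Z=1")
        data = data[None, None, None]
    elif data.ndim == 3:
        warnings.warn("3D image promoted to C=1, T=1")
        data = data[None, None]
    elif data.ndim == 4:
        data = data[None]
    elif data.ndim != 5:
        raise ValueError(f"cannot interpret {data.ndim}-dimensional TIFF")
    if voxel_size_um is None:
        if "voxel_size_um" not in meta:
            raise ValueError("no voxel size in metadata and no override given")
        voxel_size_um = tuple(meta["voxel_size_um"])
    if dt_s is None:
        dt_s = float(meta.get("dt_s", 0) or 0)
        if dt_s <= 0:
            raise ValueError("no frame interval in metadata and no override given")
    return TimelapseStack(data, tuple(voxel_size_um), dt_s)


def write_tracks(tracks: list[Trajectory], path) -> None:
    rows = []
    for tr in tracks:
        for f, p in zip(tr.frames, tr.positions_um):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": int(f),
                    "x_um": p[0],
                    "y_um": p[1],
                    "z_um": p[2] if tr.dims == 3 else np.nan,
                    "resolution_tag": tr.resolution_tag,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks(path, dt_s: float) -> list[Trajectory]:
    df = pd.read_csv(path)
    tracks = []
    for tid, g in df.groupby("track_id"):
        g = g.sort_values("frame")
        dims = 2 if g["z_um"].isna().all() else 3
        cols = ["x_um", "y_um"] + (["z_um"] if dims == 3 else [])
        tag = str(g["resolution_tag"].iloc[0]) if "resolution_tag" in g and not g["resolution_tag"].isna().all() else ""
        tracks.append(
            Trajectory(
                track_id=int(tid),
                frames=g["frame"].to_numpy(),
                positions_um=g[cols].to_numpy(dtype=float),
                dt_s=dt_s,
                resolution_tag=tag,
            )
        )
    return tracks


def write_transforms(transforms, out_dir) -> None:
    """Serialise frame transforms: affines to JSON, fields to float32 TIFF."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affines = []
    for i, tf in enumerate(transforms):
        affines.append(
            {
                "frame": i,
                "matrix_row_major": np.asarray(tf.matrix).ravel().tolist(),
                "offset_px": np.asarray(tf.offset_px).tolist(),
                "note": tf.note,
            }
        )
        if tf.displacement_px is not None:
            tifffile.imwrite(
                out_dir / f"displacement_t{i:03d}.tif",
                tf.displacement_px.astype(np.float32),
            )
    (out_dir / "affines.json").write_text(json.dumps(affines, indent=1))
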