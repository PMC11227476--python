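"""Equal-area nuclear shells and location-resolved motion statistics.

The nucleus is segmented on the nucleus-channel maximum projection by Otsu
thresholding; the convex hull of the mask contour is computed with the
Jarvis-March (gift-wrapping) algorithm; and the hull polygon is scaled about
its area centroid by ``sqrt(i/N)`` for ``i = 1..N``, producing ``N`` nested
rings of exactly equal area (the area of a polygon scaled by ``s`` is
``s^2`` times the original, so ring ``i`` encloses area ``(i - (i-1))/N`` of
the hull). Shell 1 is the outermost ring, shell ``N`` the innermost region.
Each trajectory is assigned to the shell containing the majority of its
points (ties broken toward the outer shell; points outside the hull count
toward shell 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, Polygon
from shapely.prepared import prep
from skimage.filters import threshold_otsu

from .containers import Trajectory
from .motion import compare_groups

__all__ = [
    "ShellPartition",
    "segment_nucleus",
    "jarvis_march",
    "polygon_area_centroid",
    "make_shells",
    "assign_tracks",
    "per_shell_stats",
]


@dataclass
class ShellPartition:
    """N nested polygons; ``polygons[0]`` is the hull (shell 1's outer rim)."""

    n_shells: int
    polygons: list[np.ndarray]  # outermost first, each (m, 2) in µm (x, y)
    centroid_um: np.ndarray

    def shell_of_points(self, xy_um: np.ndarray) -> np.ndarray:
        """Shell index (1..N) per point; outside the hull -> shell 1."""
        xy = np.atleast_2d(xy_um)
        shell = np.ones(len(xy), dtype=int)
        preps = [prep(Polygon(p)) for p in self.polygons]
        for j, pg in enumerate(preps):  # j=0 hull ... j=N-1 innermost
            inside = np.array([pg.covers(Point(p)) for p in xy])
            # a point inside polygon j lies at least in shell j+1
            shell = np.where(inside, j + 1, shell)
        return shell


def segment_nucleus(frame_2d: np.ndarray) -> np.ndarray:
    """Otsu-threshold a 2D nucleus image; keep the largest component, fill holes."""
    img = np.asarray(frame_2d, dtype=float)
    if img.max() == img.min():
        raise ValueError("uniform image: cannot segment nucleus")
    mask = img > threshold_otsu(img)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("empty nucleus mask")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return ndimage.binary_fill_holes(labels == largest)


def jarvis_march(points: np.ndarray) -> np.ndarray:
    """Convex hull by gift wrapping; returns hull vertices counter-clockwise."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        raise ValueError("need at least 3 distinct points for a hull")
    # start from the lowest-then-leftmost point
    start = np.lexsort((pts[:, 0], pts[:, 1]))[0]
    hull = [start]
    current = start
    while True:
        # wrap: the next hull vertex Q is such that every point lies to the
        # left of current->Q; improve the candidate until no point remains
        # strictly to its right (vectorised scan, converges in a few steps)
        rel = pts - pts[current]
        d2 = np.sum(rel**2, axis=1)
        candidate = (current + 1) % len(pts)
        while True:
            c = rel[candidate]
            cross = c[0] * rel[:, 1] - c[1] * rel[:, 0]
            right = np.nonzero(cross < 0)[0]
            if len(right):
                candidate = int(right[np.argmin(cross[right] / np.sqrt(d2[right]))])
                continue
            # collinear ties: take the farthest point along the direction
            coll = np.nonzero((cross == 0) & (d2 > 0))[0]
            candidate = int(coll[np.argmax(d2[coll])])
            break
        current = candidate
        if current == start:
            break
        hull.append(current)
        if len(hull) > len(pts):  # safety: degenerate input
            raise RuntimeError("gift wrapping failed to close")
    if len(hull) < 3:
        raise ValueError("degenerate hull")
    return pts[hull]


def polygon_area_centroid(poly: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed shoelace area (absolute value returned) and area centroid."""
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if a == 0:
        raise ValueError("zero-area polygon")
    cx = np.sum((x + xn) * cross) / (6 * a)
    cy = np.sum((y + yn) * cross) / (6 * a)
    return abs(a), np.array([cx, cy])


def make_shells(
    mask: np.ndarray,
    n_shells: int = 7,
    voxel_size_yx_um: tuple[float, float] = (1.0, 1.0),
) -> ShellPartition:
    """Build N nested equal-area shell polygons from a nucleus mask.

    The hull is computed on the mask's contour pixels (mask minus its
    erosion), in µm coordinates.
    """
    if not (2 <= n_shells):
        raise ValueError("need at least 2 shells")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    contour = mask & ~ndimage.binary_erosion(mask)
    yx = np.argwhere(contour)
    vy, vx = voxel_size_yx_um
    pts = np.stack([yx[:, 1] * vx, yx[:, 0] * vy], axis=1)  # (x, y) µm
    hull = jarvis_march(pts)
    _, c = polygon_area_centroid(hull)
    polygons = [
        c + np.sqrt(i / n_shells) * (hull - c) for i in range(n_shells, 0, -1)
    ]
    return ShellPartition(n_shells=n_shells, polygons=polygons, centroid_um=c)


def assign_tracks(tracks: list[Trajectory], partition: ShellPartition) -> dict[int, int]:
    """Assign each track to the shell holding the majority of its points.

    Ties go to the outer (smaller-index) shell.
    """
    out = {}
    for tr in tracks:
        shells = partition.shell_of_points(tr.positions_um[:, :2])
        counts = np.bincount(shells, minlength=partition.n_shells + 1)
        out[tr.track_id] = int(np.argmax(counts))  # argmax takes first (outer) on ties
    return out


def per_shell_stats(
    properties: pd.DataFrame,
    shell_of_track: dict[int, int],
    value_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-shell summary statistics and shell-1-vs-others rank-sum tests.

    ``properties`` must carry a ``track_id`` column plus numeric property
    columns (e.g. the output of ``motion_properties_table``, optionally with
    an ``alpha`` column merged in). Returns ``(summary, pvalues)``; p-values
    are NaN where a shell has fewer than 2 tracks.
    """
    df = properties.copy()
    df["shell"] = df["track_id"].map(shell_of_track)
    if value_columns is None:
        value_columns = [
            c for c in df.columns if c not in ("track_id", "shell") and np.issubdtype(df[c].dtype, np.number)
        ]
    grouped = df.groupby("shell")
    summary = grouped[value_columns].agg(["count", "mean", "median"])
    shells = sorted(df["shell"].dropna().unique())
    rows = []
    ref = df[df["shell"] == 1]
    for s in shells:
        if s == 1:
            continue
        other = df[df["shell"] == s]
        row = {"shell": s}
        for col in value_columns:
            a, b = ref[col].dropna(), other[col].dropna()
            row[col] = (
                compare_groups(a, b) if len(a) >= 2 and len(b) >= 2 else np.nan
            )
        rows.append(row)
    pvals = pd.DataFrame(rows).set_index("shell") if rows else pd.DataFrame()
    return summary, pvals
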