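"""MSD analysis, diffusion / anomalous-diffusion fitting and track statistics.

The mean squared displacement of a trajectory is the time average

    MSD(k·dt) = < |r(t + k·dt) - r(t)|^2 >_t

over all ordered position pairs separated by lag ``k·dt``. Two models are
fitted independently to each curve:

* free diffusion, ``MSD = 2 d D Δt`` (``d`` = spatial dimensionality, so
  ``6 D Δt`` for 3D foci and ``4 D Δt`` for 2D territories), by weighted
  least squares through the origin;
* anomalous diffusion, ``MSD = Γ Δt^α``, by weighted linear regression of
  ``log MSD`` on ``log Δt`` (α = slope, Γ = exp(intercept)).

Weights are the pair counts per lag. α < 1 indicates constrained motion,
α ≈ 1 free diffusion and α > 1 directed motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import Trajectory

__all__ = [
    "MSDCurve",
    "MotionFit",
    "MotionProperties",
    "msd",
    "ensemble_msd",
    "fit_diffusion",
    "fit_anomalous",
    "motion_properties",
    "motion_properties_table",
    "per_track_alpha",
    "compare_groups",
]


@dataclass
class MSDCurve:
    """MSD(Δt) with supporting pair counts.

    ``lags_s`` excludes lag 0 (MSD(0) ≡ 0 by definition).
    """

    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    dims: int

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=float)
        if not (len(self.lags_s) == len(self.msd_um2) == len(self.n_pairs)):
            raise ValueError("lags, msd and n_pairs must align")


@dataclass
class MotionFit:
    D_um2_s: float | None = None
    D_flag: str = ""
    alpha: float | None = None
    gamma: float | None = None
    fit_lags_s: np.ndarray | None = None
    residual: float | None = None


@dataclass
class MotionProperties:
    radius_of_gyration_um: float
    mean_velocity_um_s: float
    distance_start_end_um: float
    straightness: float
    flag: str = ""


def msd(track: Trajectory, max_lag_frames: int | None = None) -> MSDCurve:
    """Time-averaged MSD of one trajectory; gap-aware via frame indices."""
    frames = track.frames
    pos = track.positions_um
    span = int(frames[-1] - frames[0])
    if span < 1:
        raise ValueError("track too short for any lag")
    max_lag = span if max_lag_frames is None else min(max_lag_frames, span)
    lags, vals, counts = [], [], []
    if len(frames) == span + 1:  # gapless: direct vectorized pairs
        for k in range(1, max_lag + 1):
            d2 = np.sum((pos[k:] - pos[:-k]) ** 2, axis=1)
            lags.append(k * track.dt_s)
            vals.append(float(d2.mean()))
            counts.append(len(d2))
    else:
        idx = {int(f): j for j, f in enumerate(frames)}
        for k in range(1, max_lag + 1):
            d2 = [
                np.sum((pos[idx[f + k]] - pos[idx[f]]) ** 2)
                for f in idx
                if f + k in idx
            ]
            if d2:
                lags.append(k * track.dt_s)
                vals.append(float(np.mean(d2)))
                counts.append(len(d2))
    return MSDCurve(np.array(lags), np.array(vals), np.array(counts), dims=track.dims)


def ensemble_msd(tracks: list[Trajectory], max_lag_frames: int | None = None) -> MSDCurve:
    """Unweighted mean of per-track MSDs at each lag.

    A track contributes to a lag only if it is long enough for that lag;
    ``n_pairs`` accumulates the total ordered pairs across contributing
    tracks (used as fit weights).
    """
    if not tracks:
        raise ValueError("no tracks")
    per: dict[float, list[tuple[float, int]]] = {}
    dims = tracks[0].dims
    for tr in tracks:
        try:
            c = msd(tr, max_lag_frames)
        except ValueError:
            continue
        for lag, m, n in zip(c.lags_s, c.msd_um2, c.n_pairs):
            per.setdefault(float(lag), []).append((m, int(n)))
    if not per:
        raise ValueError("no track long enough for any lag")
    lags = np.array(sorted(per))
    vals = np.array([np.mean([m for m, _ in per[l]]) for l in lags])
    counts = np.array([sum(n for _, n in per[l]) for l in lags])
    return MSDCurve(lags, vals, counts, dims=dims)


def fit_diffusion(curve: MSDCurve) -> MotionFit:
    """Weighted least-squares slope of MSD vs Δt through the origin.

    ``D = slope / (2 d)``; a negative fitted slope is reported as ``D = 0``
    with a flag.
    """
    if len(curve.lags_s) < 2:
        raise ValueError("need at least 2 lags")
    w, t, m = curve.n_pairs, curve.lags_s, curve.msd_um2
    slope = float(np.sum(w * t * m) / np.sum(w * t * t))
    fit = MotionFit(fit_lags_s=curve.lags_s)
    if slope < 0:
        fit.D_um2_s, fit.D_flag = 0.0, "negative_slope"
    else:
        fit.D_um2_s = slope / (2 * curve.dims)
    fit.residual = float(np.sum(w * (m - slope * t) ** 2) / np.sum(w))
    return fit


def fit_anomalous(curve: MSDCurve) -> MotionFit:
    """Weighted log-log regression: α = slope, Γ = exp(intercept).

    Lags with non-positive MSD are dropped; at least 3 usable lags are
    required.
    """
    keep = curve.msd_um2 > 0
    if keep.sum() < 3:
        raise ValueError("need at least 3 positive-MSD lags")
    t = np.log(curve.lags_s[keep])
    y = np.log(curve.msd_um2[keep])
    w = curve.n_pairs[keep]
    wt = np.sum(w)
    tbar, ybar = np.sum(w * t) / wt, np.sum(w * y) / wt
    denom = np.sum(w * (t - tbar) ** 2)
    alpha = float(np.sum(w * (t - tbar) * (y - ybar)) / denom)
    intercept = ybar - alpha * tbar
    fit = MotionFit(alpha=alpha, gamma=float(np.exp(intercept)), fit_lags_s=curve.lags_s[keep])
    fit.residual = float(np.sum(w * (y - alpha * t - intercept) ** 2) / wt)
    return fit


def motion_properties(track: Trajectory) -> MotionProperties:
    """Radius of gyration, mean velocity, start-end distance, straightness."""
    pos = track.positions_um
    if len(pos) < 2:
        raise ValueError("need at least 2 points")
    centroid = pos.mean(axis=0)
    rg = float(np.sqrt(np.mean(np.sum((pos - centroid) ** 2, axis=1))))
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    step_frames = np.diff(track.frames)
    mean_v = float(np.mean(steps / (step_frames * track.dt_s)))
    dse = float(np.linalg.norm(pos[-1] - pos[0]))
    path = float(steps.sum())
    if path == 0.0:
        return MotionProperties(rg, mean_v, dse, 0.0, flag="zero_path")
    return MotionProperties(rg, mean_v, dse, dse / path)


def motion_properties_table(tracks: list[Trajectory]):
    """Per-track properties as a pandas DataFrame keyed by track_id."""
    import pandas as pd

    rows = []
    for tr in tracks:
        p = motion_properties(tr)
        rows.append(
            {
                "track_id": tr.track_id,
                "radius_of_gyration_um": p.radius_of_gyration_um,
                "mean_velocity_um_s": p.mean_velocity_um_s,
                "distance_start_end_um": p.distance_start_end_um,
                "straightness": p.straightness,
            }
        )
    return pd.DataFrame(rows)


def per_track_alpha(tracks: list[Trajectory]) -> np.ndarray:
    """Per-track anomalous exponent, fitted on lags up to half the duration.

    Tracks whose fit fails (too few usable lags) yield NaN.
    """
    out = np.full(len(tracks), np.nan)
    for i, tr in enumerate(tracks):
        half = max(tr.n_steps // 2, 3)
        try:
            out[i] = fit_anomalous(msd(tr, max_lag_frames=half)).alpha
        except ValueError:
            pass
    return out


def compare_groups(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two samples.

    Exact enumeration (no ties) for min(n) <= 8, otherwise the normal
    approximation with tie correction. Identical constant groups give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    if min(len(a), len(b)) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
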