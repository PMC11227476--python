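"""Parameter-recovery benchmarks on fully synthetic ground truth.

Because suitable public raw movies do not exist at desk scale, the
pipeline's accuracy is demonstrated by simulating trajectories (and full
image stacks) at published parameter values and measuring how well each
stage of the pipeline recovers them. Every benchmark seeds all randomness
explicitly and runs in seconds on one CPU.
"""

from __future__ import annotations

import numpy as np

from . import detection, motion, subpop, tracking
from .containers import Trajectory
from .simulate import MotionSpec, SceneConfig, render_timelapse, simulate_tracks

__all__ = [
    "alpha_recovery",
    "diffusion_recovery",
    "end_to_end_focus_diffusion",
    "end_to_end_territory_diffusion",
    "subpopulation_centroids",
    "fixed_control_msd_ratio",
]


def alpha_recovery(
    alpha: float,
    n_tracks: int = 1000,
    n_frames: int = 12,
    dt_s: float = 10.0,
    dims: int = 3,
    D: float = 8.32e-5,
    seed: int = 1,
) -> float:
    """Fitted ensemble log-log MSD exponent from simulated fBm tracks."""
    spec = MotionSpec(model="anomalous", D=D, alpha=alpha, dims=dims, dt_s=dt_s, n_frames=n_frames, seed=seed)
    tracks = simulate_tracks(spec, n_tracks)
    return float(motion.fit_anomalous(motion.ensemble_msd(tracks)).alpha)


def diffusion_recovery(
    D: float,
    n_tracks: int = 1000,
    n_frames: int = 12,
    dt_s: float = 10.0,
    dims: int = 3,
    seed: int = 1,
) -> float:
    """Fitted diffusion coefficient (µm²/s) from simulated Brownian tracks."""
    spec = MotionSpec(model="brownian", D=D, dims=dims, dt_s=dt_s, n_frames=n_frames, seed=seed)
    tracks = simulate_tracks(spec, n_tracks)
    return float(motion.fit_diffusion(motion.ensemble_msd(tracks)).D_um2_s)


def _focus_movie_tracks(D: float, seed: int, n_spots: int, model: str = "brownian"):
    """Render one SIM-like movie of diffusing foci and track it back.

    The gate radius (0.3 µm, ~7x the per-frame step) keeps occasional
    sub-resolution encounters from being bridged as spurious long jumps.
    """
    cfg = SceneConfig(seed=seed)
    cx, cy, cz = cfg.nucleus_center_um
    spec = MotionSpec(model=model, D=D, seed=seed)
    tracks = simulate_tracks(
        spec, n_spots, start_region=(np.array([cx, cy, cz]), np.array([2.6, 2.6, 0.25]))
    )
    stack, _ = render_timelapse(tracks, cfg)
    params = detection.SEFParams(log_sigma_um=cfg.psf_sigma_um, k=3.0)
    dets = detection.sef_detect_sequence(stack, channel=1, params=params)
    linked = tracking.track_foci(dets, gate_radius_um=0.3, max_gap=1, dt_s=cfg.dt_s)
    return tracking.filter_tracks(linked)


def end_to_end_focus_diffusion(
    D: float = 8.32e-5, seed: int = 1, n_movies: int = 3, n_spots: int = 28
) -> float:
    """D recovered through rendering, SEF detection, linking and fitting."""
    pooled = []
    for m in range(n_movies):
        pooled.extend(_focus_movie_tracks(D, seed * 1000 + m, n_spots))
    curve = motion.ensemble_msd(pooled)
    return float(motion.fit_diffusion(curve).D_um2_s)


def end_to_end_territory_diffusion(
    D: float = 3.18e-5, seed: int = 1, n_movies: int = 5, n_blobs: int = 5
) -> float:
    """D recovered through territory rendering, DoG segmentation on max
    projections, mutual-NN tracking and the 2D diffusion fit."""
    starts = [(3.5, 4.0), (8.0, 4.0), (12.5, 4.0), (3.5, 11.0), (8.0, 11.0)][:n_blobs]
    pooled = []
    for m in range(n_movies):
        cfg = SceneConfig(
            shape_tzyx=(12, 5, 192, 192),
            voxel_size_um=(0.25, 0.082, 0.082),
            psf_sigma_um=(0.5, 0.45, 0.45),
            spot_amplitude=120.0,
            nucleus_amplitude=0.0,
            nucleus_texture=0.0,
            seed=seed * 100 + m,
        )
        rng = np.random.default_rng([seed, 17, m])
        spec = MotionSpec(model="brownian", D=D, dims=2, seed=0)
        trs = []
        for i, (x, y) in enumerate(starts):
            tr = simulate_tracks(spec, 1, rng=rng)[0]
            tr.positions_um = tr.positions_um + np.array([x, y])
            tr.track_id = i
            trs.append(tr)
        stack, _ = render_timelapse(trs, cfg)
        cents = detection.segment_territories(stack, channel=1, dog_sigmas_um=(0.3, 1.2))
        linked = tracking.track_territories(cents, gate_radius_um=1.0, dt_s=cfg.dt_s)
        pooled.extend(tracking.filter_tracks(linked))
    curve = motion.ensemble_msd(pooled)
    return float(motion.fit_diffusion(curve).D_um2_s)


def subpopulation_centroids(
    means: tuple[float, float],
    sd: float = 0.15,
    n_per_group: int = 300,
    n_frames: int = 100,
    dt_s: float = 10.0,
    seed: int = 1,
) -> np.ndarray:
    """k-means++ centroids of per-track fitted α from a two-group mixture.

    Each track's true exponent is drawn from a normal spread around its
    group mean (clipped to the admissible range); per-track α is then
    *fitted* from the track's own time-averaged MSD, so the clustering sees
    realistic estimation noise.
    """
    rng = np.random.default_rng(seed)
    tracks: list[Trajectory] = []
    for mean in means:
        alphas = np.clip(rng.normal(mean, sd, n_per_group), 0.05, 2.0)
        for a in alphas:
            spec = MotionSpec(
                model="anomalous", D=8e-5, alpha=float(a), n_frames=n_frames, dt_s=dt_s
            )
            tracks.extend(simulate_tracks(spec, 1, rng=rng))
    fitted = motion.per_track_alpha(tracks)
    res = subpop.cluster_alpha(fitted, k=2, seed=seed, n_init=10)
    return res.centroids


def fixed_control_msd_ratio(seed: int = 1, n_spots: int = 40) -> float:
    """MSD(11·dt) / MSD(dt) of a noise-limited immobile (fixed-cell) scene
    passed through the full detection + tracking pipeline. Flat (≈1) means
    the apparent motion floor is localisation noise, not drift."""
    tracks = _focus_movie_tracks(D=0.0, seed=seed, n_spots=n_spots, model="immobile")
    curve = motion.ensemble_msd(tracks)
    return float(curve.msd_um2[-1] / curve.msd_um2[0])
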