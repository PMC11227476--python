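"""Synthetic ground-truthed data emulating correlative chromatin imaging.

This module generates everything the downstream pipeline consumes, with
known truth attached, so detection, tracking, registration, motion fitting
and DNA quantification can all be validated without real microscopy data:

* trajectories following immobile / Brownian / anomalous (fractional
  Brownian) / directed motion models,
* rendered two-channel 3D time-lapse stacks (nucleus marker + labeled
  chromatin foci) at a SIM-like (~120 nm lateral) or widefield-like
  (~240 nm lateral) resolution regime, with Poisson-Gaussian noise,
* global cell motion (per-frame affine plus a smooth deformation field),
* fixed-cell scenes for DNA-content-per-focus quantification in which each
  focus carries a prescribed fraction of the total DNA-stain intensity.

The anomalous model is exact fractional Brownian motion: per axis the
position process satisfies ``E[(x(t+D)-x(t))^2] = 2 D |D|^alpha``, realised
by a Cholesky factorisation of the closed-form position covariance
``Cov(x_t, x_s) = D (t^a + s^a - |t-s|^a)``. ``alpha = 1`` is the Brownian
special case; directed motion adds a constant drift to a Brownian track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .containers import TimelapseStack, Trajectory

__all__ = [
    "MotionSpec",
    "SceneConfig",
    "GroundTruth",
    "SinusoidalDeformation",
    "SIM_PSF_SIGMA_UM",
    "WF_PSF_SIGMA_UM",
    "position_covariance",
    "simulate_tracks",
    "make_global_motion",
    "apply_global_motion_tracks",
    "apply_global_motion_stack",
    "render_timelapse",
    "make_dna_scene",
]

#: Gaussian PSF sigma (z, y, x) in µm for the two resolution regimes.
#: Lateral values correspond to FWHM ≈ 120 nm (SIM-like) and ≈ 240 nm
#: (widefield-like); axial resolution is poorer in both regimes.
SIM_PSF_SIGMA_UM: tuple[float, float, float] = (0.15, 0.051, 0.051)
WF_PSF_SIGMA_UM: tuple[float, float, float] = (0.30, 0.102, 0.102)


@dataclass(frozen=True)
class MotionSpec:
    """Parameters of one motion model.

    ``D`` is the (generalized) diffusion coefficient in µm²/s^alpha such
    that the per-axis MSD is ``2 D dt^alpha`` (so the 3D MSD is
    ``6 D dt^alpha``).
    """

    model: str = "brownian"  # anomalous | brownian | directed | immobile
    D: float = 8.32e-5
    alpha: float = 1.0
    drift_um_s: tuple[float, ...] = (0.0, 0.0, 0.0)
    dims: int = 3
    dt_s: float = 10.0
    n_frames: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in {"anomalous", "brownian", "directed", "immobile"}:
            raise ValueError(f"unknown motion model {self.model!r}")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if not (0.0 < self.alpha <= 2.0):
            raise ValueError("alpha must lie in (0, 2]")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")

    def effective(self) -> "MotionSpec":
        """Resolve model aliases: brownian/directed → alpha 1, immobile → D 0."""
        out = self
        if self.model in ("brownian", "directed"):
            out = replace(out, alpha=1.0)
        if self.model == "immobile":
            out = replace(out, D=0.0)
        return out


def position_covariance(times_s: np.ndarray, D: float, alpha: float) -> np.ndarray:
    """Closed-form per-axis position covariance of fBm started at 0.

    ``Cov(x_t, x_s) = D (t^a + s^a - |t-s|^a)``, which reproduces the
    stationary-increment law ``E[(x_t-x_s)^2] = 2 D |t-s|^a``.
    """
    t = np.asarray(times_s, dtype=float)
    ta = t**alpha
    return D * (ta[:, None] + ta[None, :] - np.abs(t[:, None] - t[None, :]) ** alpha)


def _sample_ellipsoid(rng: np.ndarray, n: int, center: np.ndarray, semi: np.ndarray):
    """Uniform points inside an axis-aligned ellipsoid (rejection sampling)."""
    dims = len(center)
    out = np.empty((n, dims))
    got = 0
    while got < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n - got) + 8, dims))
        keep = cand[np.sum(cand**2, axis=1) <= 1.0]
        take = min(len(keep), n - got)
        out[got : got + take] = keep[:take]
        got += take
    return center + out * semi


def simulate_tracks(
    spec: MotionSpec,
    n_tracks: int,
    start_region: tuple[np.ndarray, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> list[Trajectory]:
    """Simulate ``n_tracks`` trajectories under ``spec``.

    Parameters
    ----------
    start_region
        Optional ``(center, semi_axes)`` of an axis-aligned ellipsoid (µm)
        in which starting positions are drawn uniformly; all tracks start at
        the origin when omitted.
    rng
        Overrides ``spec.seed`` when given (used by composite generators).
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    spec = spec.effective()
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    times = np.arange(spec.n_frames) * spec.dt_s
    if start_region is None:
        starts = np.zeros((n_tracks, spec.dims))
    else:
        center, semi = (np.asarray(a, dtype=float) for a in start_region)
        starts = _sample_ellipsoid(rng, n_tracks, center[: spec.dims], semi[: spec.dims])

    if spec.D > 0:
        cov = position_covariance(times[1:], spec.D, spec.alpha)
        # jitter guards the factorization near alpha = 2 where the
        # covariance approaches rank 1; fall back to a clipped
        # eigendecomposition for exactly singular cases
        jitter = 1e-12 * float(np.max(np.diag(cov)))
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(len(cov)))
        except np.linalg.LinAlgError:
            vals, vecs = np.linalg.eigh(cov)
            chol = vecs * np.sqrt(np.clip(vals, 0.0, None))
    else:
        chol = None

    drift = np.asarray(spec.drift_um_s[: spec.dims], dtype=float)
    tracks: list[Trajectory] = []
    frames = np.arange(spec.n_frames)
    for i in range(n_tracks):
        pos = np.tile(starts[i], (spec.n_frames, 1))
        if chol is not None:
            z = rng.standard_normal((len(times) - 1, spec.dims))
            pos[1:] += chol @ z
        if spec.model == "directed":
            pos += times[:, None] * drift[None, :]
        tracks.append(
            Trajectory(track_id=i, frames=frames.copy(), positions_um=pos, dt_s=spec.dt_s)
        )
    return tracks


# ---------------------------------------------------------------------------
# global motion


@dataclass(frozen=True)
class SinusoidalDeformation:
    """Smooth band-limited in-plane deformation ``u(x, y)``.

    Displacement in µm:
    ``u_x = a_x sin(2π y / L + φ)``, ``u_y = a_y sin(2π x / L + φ)``.
    """

    amplitude_um: tuple[float, float] = (0.0, 0.0)
    wavelength_um: float = 5.0
    phase: float = 0.0

    def __call__(self, xy_um: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy_um)
        w = 2.0 * math.pi / self.wavelength_um
        ux = self.amplitude_um[0] * np.sin(w * xy[:, 1] + self.phase)
        uy = self.amplitude_um[1] * np.sin(w * xy[:, 0] + self.phase)
        return np.stack([ux, uy], axis=1)


def make_global_motion(
    n_frames: int,
    translation_per_frame_um: tuple[float, float] = (0.0, 0.0),
    rotation_per_frame_deg: float = 0.0,
    rotation_center_um: tuple[float, float] = (0.0, 0.0),
    deformation_amplitude_um: float = 0.0,
    deformation_wavelength_um: float = 5.0,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[SinusoidalDeformation]]:
    """Build a per-frame affine series and deformation series.

    Frame 0 is the identity; motion accumulates linearly with frame index,
    emulating steady cell drift/rotation plus a growing smooth deformation.
    Affines are ``(A, b)`` acting on (x, y) µm coordinates as ``A p + b``.
    """
    affines = []
    deforms = []
    cx, cy = rotation_center_um
    c = np.array([cx, cy])
    for t in range(n_frames):
        theta = math.radians(rotation_per_frame_deg * t)
        A = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        b = c - A @ c + t * np.asarray(translation_per_frame_um, dtype=float)
        affines.append((A, b))
        amp = deformation_amplitude_um * t / max(n_frames - 1, 1)
        deforms.append(
            SinusoidalDeformation((amp, amp), deformation_wavelength_um, phase=0.0)
        )
    return affines, deforms


def _check_motion(affine_series, deformation_series, n_frames):
    if len(affine_series) != n_frames:
        raise ValueError("need one affine per frame")
    if deformation_series is not None and len(deformation_series) != n_frames:
        raise ValueError("need one deformation per frame")
    for A, _ in affine_series:
        if abs(np.linalg.det(np.asarray(A))) < 1e-12:
            raise ValueError("affine must be invertible")


def _move_xy(xy: np.ndarray, affine, deform) -> np.ndarray:
    A, b = affine
    out = xy @ np.asarray(A).T + np.asarray(b)
    if deform is not None:
        out = out + deform(out)
    return out


def apply_global_motion_tracks(
    tracks: list[Trajectory],
    affine_series,
    deformation_series=None,
) -> list[Trajectory]:
    """Apply per-frame global motion (affine, then deformation) to tracks.

    Only the (x, y) components move; z is preserved, matching the in-plane
    character of whole-cell drift in shallow sub-volume imaging.
    """
    n_frames = 1 + max(int(tr.frames.max()) for tr in tracks)
    _check_motion(affine_series, deformation_series, n_frames)
    moved = []
    for tr in tracks:
        pos = tr.positions_um.copy()
        for j, f in enumerate(tr.frames):
            deform = deformation_series[f] if deformation_series is not None else None
            pos[j, :2] = _move_xy(pos[j, :2][None, :], affine_series[f], deform)[0]
        moved.append(replace(tr, positions_um=pos))
    return moved


def _inverse_map_xy(xy: np.ndarray, affine, deform) -> np.ndarray:
    """Invert affine-then-deformation at the given moved coordinates.

    The deformation inverse uses two fixed-point iterations, accurate to
    O(|u|·|∇u|) for the smooth, small-amplitude fields generated here.
    """
    y = xy
    if deform is not None:
        y0 = xy - deform(xy)
        y = xy - deform(y0)
    A, b = affine
    Ainv = np.linalg.inv(np.asarray(A))
    return (y - np.asarray(b)) @ Ainv.T


def apply_global_motion_stack(
    stack: TimelapseStack,
    affine_series,
    deformation_series=None,
) -> TimelapseStack:
    """Resample every channel/frame of a stack through the global motion.

    Voxels that map outside the field of view are filled with the per-frame
    background median.
    """
    _check_motion(affine_series, deformation_series, stack.n_frames)
    vz, vy, vx = stack.voxel_size_um
    _, _, Z, Y, X = stack.data.shape
    yy, xx = np.meshgrid(np.arange(Y) * vy, np.arange(X) * vx, indexing="ij")
    grid_xy = np.stack([xx.ravel(), yy.ravel()], axis=1)
    out = stack.data.copy()
    for t in range(stack.n_frames):
        deform = deformation_series[t] if deformation_series is not None else None
        A, b = affine_series[t]
        if deform is None and np.allclose(A, np.eye(2)) and np.allclose(b, 0):
            continue
        src_xy = _inverse_map_xy(grid_xy, affine_series[t], deform)
        iy = (src_xy[:, 1] / vy).reshape(Y, X)
        ix = (src_xy[:, 0] / vx).reshape(Y, X)
        for c in range(stack.n_channels):
            fill = float(np.median(stack.data[c, t]))
            for z in range(Z):
                out[c, t, z] = ndimage.map_coordinates(
                    stack.data[c, t, z], [iy, ix], order=1, mode="constant", cval=fill
                )
    return TimelapseStack(out, stack.voxel_size_um, stack.dt_s)


# ---------------------------------------------------------------------------
# rendering


@dataclass
class SceneConfig:
    """Geometry, optics and noise of a rendered two-channel time-lapse."""

    shape_tzyx: tuple[int, int, int, int] = (12, 7, 192, 192)
    voxel_size_um: tuple[float, float, float] = (0.125, 0.041, 0.041)
    psf_sigma_um: tuple[float, float, float] = SIM_PSF_SIGMA_UM
    spot_amplitude: float = 200.0
    background: float = 20.0
    read_noise_sigma: float = 2.0
    poisson_noise: bool = True
    nucleus_center_um: tuple[float, float, float] | None = None  # (x, y, z)
    nucleus_semiaxes_um: tuple[float, float, float] = (3.2, 3.2, 2.0)
    nucleus_amplitude: float = 80.0
    #: relative amplitude of the granular intra-nuclear texture (the
    #: replication-machinery marker is punctate, which is what anchors
    #: non-rigid registration on real data)
    nucleus_texture: float = 0.4
    texture_sigma_um: float = 0.12
    dt_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.nucleus_center_um is None:
            T, Z, Y, X = self.shape_tzyx
            vz, vy, vx = self.voxel_size_um
            self.nucleus_center_um = (
                (X - 1) * vx / 2.0,
                (Y - 1) * vy / 2.0,
                (Z - 1) * vz / 2.0,
            )


@dataclass
class GroundTruth:
    """Everything needed to score detection, tracking and registration."""

    tracks_ref: list[Trajectory] = field(default_factory=list)
    tracks_moved: list[Trajectory] = field(default_factory=list)
    affine_series: list | None = None
    deformation_series: list | None = None
    clipped: list[tuple[int, int]] = field(default_factory=list)
    focus_fractions: np.ndarray | None = None
    focus_masks: np.ndarray | None = None  # labeled volume for DNA scenes
    nucleus_mask: np.ndarray | None = None
    config: object | None = None
    seed: int = 0


def _add_gaussian_spot(vol, center_um, sigma_um, amplitude, voxel_size_um):
    """Accumulate an anisotropic Gaussian into a (Z, Y, X) volume in place.

    Returns False when the spot centre lies outside the field of view.
    """
    vz, vy, vx = voxel_size_um
    x, y, z = center_um
    Z, Y, X = vol.shape
    cz, cy, cx = z / vz, y / vy, x / vx
    inside = (0 <= cz <= Z - 1) and (0 <= cy <= Y - 1) and (0 <= cx <= X - 1)
    sz, sy, sx = sigma_um[0] / vz, sigma_um[1] / vy, sigma_um[2] / vx
    half = (int(4 * sz) + 2, int(4 * sy) + 2, int(4 * sx) + 2)
    lo = [max(0, int(c) - h) for c, h in zip((cz, cy, cx), half)]
    hi = [min(n, int(c) + h + 1) for c, n, h in zip((cz, cy, cx), (Z, Y, X), half)]
    if any(l >= h for l, h in zip(lo, hi)):
        return inside
    zz = (np.arange(lo[0], hi[0]) - cz) / sz
    yy = (np.arange(lo[1], hi[1]) - cy) / sy
    xx = (np.arange(lo[2], hi[2]) - cx) / sx
    g = np.exp(
        -0.5
        * (
            zz[:, None, None] ** 2
            + yy[None, :, None] ** 2
            + xx[None, None, :] ** 2
        )
    )
    vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * g
    return inside


def _reference_nucleus(config: SceneConfig) -> np.ndarray:
    """Render the frame-1 nucleus: soft-edged ellipsoid with granular texture.

    The texture is generated from ``config.seed`` (independently of the
    noise stream) and is static in the cell frame, so it moves rigidly with
    the global motion — the property non-rigid registration relies on.
    """
    T, Z, Y, X = config.shape_tzyx
    vz, vy, vx = config.voxel_size_um
    cx, cy, cz = config.nucleus_center_um
    ax, ay, az = config.nucleus_semiaxes_um
    yy, xx = np.meshgrid(np.arange(Y) * vy, np.arange(X) * vx, indexing="ij")
    r2_xy = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
    vol = np.empty((Z, Y, X))
    for z in range(Z):
        vol[z] = (r2_xy + (((z * vz) - cz) / az) ** 2 <= 1.0).astype(float)
    if config.nucleus_texture > 0:
        trng = np.random.default_rng([int(config.seed), 7])
        noise = trng.standard_normal((Z, Y, X))
        sig_t = (
            config.texture_sigma_um / vz,
            config.texture_sigma_um / vy,
            config.texture_sigma_um / vx,
        )
        tex = ndimage.gaussian_filter(noise, sig_t)
        tex /= max(tex.std(), 1e-12)
        vol = vol * (1.0 + config.nucleus_texture * tex).clip(0.0, None)
    sig = (config.psf_sigma_um[0] / vz, config.psf_sigma_um[1] / vy, config.psf_sigma_um[2] / vx)
    return config.nucleus_amplitude * ndimage.gaussian_filter(vol, sig)


def _warp_volume_inplane(vol: np.ndarray, config: SceneConfig, affine, deform) -> np.ndarray:
    """Sample a reference volume at inverse-mapped in-plane coordinates."""
    Z, Y, X = vol.shape
    vz, vy, vx = config.voxel_size_um
    yy, xx = np.meshgrid(np.arange(Y) * vy, np.arange(X) * vx, indexing="ij")
    xy = np.stack([xx.ravel(), yy.ravel()], axis=1)
    src = _inverse_map_xy(xy, affine, deform)
    iy = (src[:, 1] / vy).reshape(Y, X)
    ix = (src[:, 0] / vx).reshape(Y, X)
    out = np.empty_like(vol)
    for z in range(Z):
        out[z] = ndimage.map_coordinates(vol[z], [iy, ix], order=1, mode="constant", cval=0.0)
    return out


def render_timelapse(
    tracks: list[Trajectory],
    config: SceneConfig,
    affine_series=None,
    deformation_series=None,
) -> tuple[TimelapseStack, GroundTruth]:
    """Render tracks into a two-channel stack (0 = nucleus, 1 = foci).

    Global motion, when given, moves both channels identically: spot centres
    are mapped through the forward motion, the nucleus is resampled through
    its inverse. Noise (Poisson on signal+background, then additive read
    noise) is applied last; a fixed ``config.seed`` gives bit-identical
    output.
    """
    T, Z, Y, X = config.shape_tzyx
    if affine_series is not None:
        _check_motion(affine_series, deformation_series, T)
        moved = apply_global_motion_tracks(tracks, affine_series, deformation_series)
    else:
        moved = tracks
    rng = np.random.default_rng(config.seed)
    data = np.zeros((2, T, Z, Y, X))
    gt = GroundTruth(
        tracks_ref=tracks,
        tracks_moved=moved,
        affine_series=affine_series,
        deformation_series=deformation_series,
        config=config,
        seed=config.seed,
    )
    ref_nucleus = _reference_nucleus(config)
    for t in range(T):
        affine = affine_series[t] if affine_series is not None else None
        deform = deformation_series[t] if deformation_series is not None else None
        if affine is None:
            data[0, t] = ref_nucleus
        else:
            data[0, t] = _warp_volume_inplane(ref_nucleus, config, affine, deform)
        for tr in moved:
            sel = np.nonzero(tr.frames == t)[0]
            if len(sel) == 0:
                continue
            p = tr.positions_um[sel[0]]
            center = (p[0], p[1], p[2] if tr.dims == 3 else config.nucleus_center_um[2])
            ok = _add_gaussian_spot(
                data[1, t], center, config.psf_sigma_um, config.spot_amplitude, config.voxel_size_um
            )
            if not ok:
                gt.clipped.append((tr.track_id, t))
    data += config.background
    if config.poisson_noise:
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
    if config.read_noise_sigma > 0:
        data = data + rng.normal(0.0, config.read_noise_sigma, size=data.shape)
    stack = TimelapseStack(data, config.voxel_size_um, config.dt_s)
    return stack, gt


# ---------------------------------------------------------------------------
# fixed-cell DNA-quantification scenes


def make_dna_scene(
    focus_fractions,
    stage: str = "mS",
    shape_zyx: tuple[int, int, int] = (48, 96, 96),
    voxel_size_um: tuple[float, float, float] = (0.25, 0.25, 0.25),
    nucleus_semiaxes_um: tuple[float, float, float] = (9.0, 9.0, 4.5),
    focus_radius_um: float = 0.6,
    base_intensity: float = 100.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[TimelapseStack, GroundTruth]:
    """Render a fixed-cell scene for DNA quantification.

    Channel 0 is a DAPI-like total-DNA stain over a nuclear ellipsoid whose
    intensity inside focus ``i`` is constructed so that (before noise) the
    summed focus intensity divided by the summed nuclear intensity equals
    ``focus_fractions[i]`` exactly; channel 1 marks the same voxels
    (the labeled-chromatin channel). Returned as a T=1 stack.
    """
    fr = np.asarray(focus_fractions, dtype=float)
    if np.any(fr <= 0):
        raise ValueError("focus fractions must be positive")
    if fr.sum() >= 1.0:
        raise ValueError("focus fractions must sum to < 1")
    rng = np.random.default_rng(seed)
    Z, Y, X = shape_zyx
    vz, vy, vx = voxel_size_um
    cz, cy, cx = (Z - 1) * vz / 2, (Y - 1) * vy / 2, (X - 1) * vx / 2
    ax, ay, az = nucleus_semiaxes_um  # (x, y, z)
    zz, yy, xx = np.meshgrid(
        np.arange(Z) * vz, np.arange(Y) * vy, np.arange(X) * vx, indexing="ij"
    )
    r2 = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2
    nucleus = r2 <= 1.0

    # drop non-overlapping spherical foci inside the nucleus
    labels = np.zeros(shape_zyx, dtype=int)
    centers = []
    tries = 0
    while len(centers) < len(fr):
        tries += 1
        if tries > 10000:
            raise RuntimeError("could not place foci without overlap")
        cand = _sample_ellipsoid(
            rng, 1, np.array([cx, cy, cz]), 0.7 * np.array([ax, ay, az])
        )[0]
        if any(np.linalg.norm(cand - c) < 2.2 * focus_radius_um for c in centers):
            continue
        centers.append(cand)
    for i, c in enumerate(centers):
        d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
        labels[(d2 <= focus_radius_um**2) & nucleus] = i + 1

    dapi = np.zeros(shape_zyx)
    n_bg = int(nucleus.sum() - (labels > 0).sum())
    total = base_intensity * n_bg / (1.0 - fr.sum())
    dapi[nucleus] = base_intensity
    for i in range(len(fr)):
        m = labels == i + 1
        if m.sum() == 0:
            raise RuntimeError("focus rendered with zero voxels; enlarge radius")
        dapi[m] = fr[i] * total / m.sum()
    focus_channel = np.where(labels > 0, 255.0, 0.0)
    if noise_sigma > 0:
        dapi = dapi + rng.normal(0, noise_sigma, size=dapi.shape)
        focus_channel = focus_channel + rng.normal(0, noise_sigma, size=dapi.shape)
    data = np.stack([dapi[None], focus_channel[None]], axis=0)  # (C, T=1, Z, Y, X)
    stack = TimelapseStack(data, voxel_size_um, dt_s=1.0)
    gt = GroundTruth(
        focus_fractions=fr,
        focus_masks=labels,
        nucleus_mask=nucleus,
        config={"stage": stage, "centers": centers, "seed": seed},
        seed=seed,
    )
    return stack, gt
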