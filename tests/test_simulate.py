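"""Generator correctness: exact fractional-Gaussian statistics, rendering
geometry, global motion, and DNA-scene construction."""

import numpy as np
import pytest

from chromomotion.simulate import (
    MotionSpec,
    SceneConfig,
    SIM_PSF_SIGMA_UM,
    WF_PSF_SIGMA_UM,
    SinusoidalDeformation,
    apply_global_motion_tracks,
    apply_global_motion_stack,
    make_dna_scene,
    make_global_motion,
    position_covariance,
    render_timelapse,
    simulate_tracks,
)


def increment_covariance_oracle(times, D, alpha):
    """Closed-form fractional-Gaussian-noise covariance of the increments.

    Independent of the generator's Cholesky path: built directly from the
    stationary-increment law Cov(dx_i, dx_j) =
    D (|Δ+dt|^a + |Δ-dt|^a - 2|Δ|^a) with Δ = t_i - t_j.
    """
    t = np.asarray(times)[:-1]
    dt = times[1] - times[0]
    lag = t[:, None] - t[None, :]
    return D * (
        np.abs(lag + dt) ** alpha + np.abs(lag - dt) ** alpha - 2 * np.abs(lag) ** alpha
    )


class TestSimulateTracks:
    def test_immobile_tracks_are_constant(self):
        tracks = simulate_tracks(MotionSpec(model="immobile", D=0.0, seed=1), 5)
        for tr in tracks:
            assert np.all(tr.positions_um == tr.positions_um[0])

    def test_brownian_ensemble_msd_recovers_D(self):
        D = 8.32e-5
        tracks = simulate_tracks(MotionSpec(model="brownian", D=D, seed=2), 1000)
        disp = np.stack([tr.positions_um[1:] - tr.positions_um[:-1] for tr in tracks])
        msd1 = np.mean(np.sum(disp**2, axis=2))  # one-step MSD
        assert msd1 / (6 * 10.0) == pytest.approx(D, rel=0.10)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.5])
    def test_increment_covariance_matches_closed_form(self, alpha):
        spec = MotionSpec(model="anomalous", D=5e-5, alpha=alpha, n_frames=8, seed=3)
        tracks = simulate_tracks(spec, 2000)
        times = tracks[0].times_s
        oracle = increment_covariance_oracle(times, spec.D, alpha)
        inc = np.concatenate(
            [np.diff(np.stack([tr.positions_um for tr in tracks]), axis=1)[..., d] for d in range(3)]
        )
        emp = (inc.T @ inc) / len(inc)
        assert np.max(np.abs(emp - oracle)) / np.max(np.abs(oracle)) < 0.05

    def test_brownian_increments_uncorrelated(self):
        tracks = simulate_tracks(MotionSpec(model="brownian", D=5e-5, seed=4), 2000)
        inc = np.diff(np.stack([tr.positions_um[:, 0] for tr in tracks]), axis=1)
        rho = np.corrcoef(inc[:, :-1].ravel(), inc[:, 1:].ravel())[0, 1]
        assert abs(rho) < 0.05

    def test_subdiffusive_loglog_slope(self):
        spec = MotionSpec(model="anomalous", D=8e-5, alpha=0.5, n_frames=100, seed=5)
        tracks = simulate_tracks(spec, 1000)
        pos = np.stack([tr.positions_um for tr in tracks])
        lags = np.arange(1, 11)
        msd = [np.mean(np.sum((pos[:, k:] - pos[:, :-k]) ** 2, axis=2)) for k in lags]
        slope = np.polyfit(np.log(lags * 10.0), np.log(msd), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)

    def test_directed_adds_drift(self):
        v = (0.01, -0.005, 0.0)
        spec = MotionSpec(model="directed", D=0.0, drift_um_s=v, seed=6)
        tr = simulate_tracks(spec, 1)[0]
        expected = np.outer(tr.times_s, v)
        np.testing.assert_allclose(tr.positions_um, expected, atol=1e-12)

    def test_seed_determinism(self):
        a = simulate_tracks(MotionSpec(seed=7), 10)
        b = simulate_tracks(MotionSpec(seed=7), 10)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions_um, tb.positions_um)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(alpha=0.0),
            dict(alpha=2.5),
            dict(n_frames=1),
            dict(D=-1e-5),
            dict(model="levy"),
        ],
    )
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            MotionSpec(**bad)

    def test_start_region_sampling(self):
        center, semi = np.array([5.0, 5.0, 2.0]), np.array([2.0, 1.0, 0.5])
        tracks = simulate_tracks(MotionSpec(seed=8), 200, start_region=(center, semi))
        starts = np.stack([tr.positions_um[0] for tr in tracks])
        assert np.all(np.sum(((starts - center) / semi) ** 2, axis=1) <= 1.0 + 1e-9)


class TestRender:
    def test_single_noiseless_spot_centroid(self):
        cfg = SceneConfig(
            shape_tzyx=(2, 7, 64, 64),
            poisson_noise=False,
            read_noise_sigma=0.0,
            background=0.0,
            nucleus_amplitude=0.0,
            seed=0,
        )
        pos = np.array([[1.3, 1.1, 0.45]])
        from chromomotion.containers import Trajectory

        tr = Trajectory(0, [0, 1], np.repeat(pos, 2, axis=0), dt_s=10.0)
        stack, gt = render_timelapse([tr], cfg)
        vol = stack.frame(1, 0)
        idx = np.indices(vol.shape).reshape(3, -1)
        w = vol.ravel()
        cz, cy, cx = (idx * w).sum(axis=1) / w.sum()
        vz, vy, vx = cfg.voxel_size_um
        assert abs(cx * vx - 1.3) < 0.1 * vx
        assert abs(cy * vy - 1.1) < 0.1 * vy
        assert abs(cz * vz - 0.45) < 0.1 * vz

    def test_resolution_regimes_merge_close_spots(self):
        """Two spots 0.2 µm apart: resolved at SIM-like width, merged at WF."""
        from chromomotion.containers import Trajectory
        from scipy import ndimage

        sep = 0.2
        maxima = {}
        for name, psf in (("sim", SIM_PSF_SIGMA_UM), ("wf", WF_PSF_SIGMA_UM)):
            cfg = SceneConfig(
                shape_tzyx=(1, 7, 96, 96),
                psf_sigma_um=psf,
                poisson_noise=False,
                read_noise_sigma=0.0,
                background=0.0,
                nucleus_amplitude=0.0,
            )
            trs = [
                Trajectory(i, [0], [[1.5 + i * sep, 1.5, 0.4]], dt_s=10.0)
                for i in range(2)
            ]
            stack, _ = render_timelapse(trs, cfg)
            plane = stack.frame(1, 0).max(axis=0)
            peaks = (plane == ndimage.maximum_filter(plane, size=5)) & (
                plane > 0.2 * plane.max()
            )
            maxima[name] = int(peaks.sum())
        assert maxima["sim"] == 2
        assert maxima["wf"] == 1

    def test_seed_determinism_bit_identical(self):
        spec = MotionSpec(seed=9)
        tracks = simulate_tracks(spec, 5)
        cfg = SceneConfig(shape_tzyx=(3, 7, 64, 64), seed=11)
        s1, _ = render_timelapse(tracks, cfg)
        s2, _ = render_timelapse(tracks, cfg)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_out_of_view_spot_flagged(self):
        from chromomotion.containers import Trajectory

        cfg = SceneConfig(shape_tzyx=(1, 7, 64, 64))
        tr = Trajectory(7, [0], [[-5.0, 1.0, 0.4]], dt_s=10.0)
        _, gt = render_timelapse([tr], cfg)
        assert (7, 0) in gt.clipped


class TestGlobalMotion:
    def test_identity_leaves_tracks_unchanged(self):
        tracks = simulate_tracks(MotionSpec(seed=10), 3)
        affines, deforms = make_global_motion(12)
        moved = apply_global_motion_tracks(tracks, affines, deforms)
        for a, b in zip(tracks, moved):
            np.testing.assert_allclose(a.positions_um, b.positions_um, atol=1e-12)

    def test_translation_equivariance(self):
        tracks = simulate_tracks(MotionSpec(seed=11, n_frames=2), 3)
        affines = [(np.eye(2), np.zeros(2)), (np.eye(2), np.array([0.5, 0.3]))]
        moved = apply_global_motion_tracks(tracks, affines)
        for a, b in zip(tracks, moved):
            np.testing.assert_allclose(
                b.positions_um[1, :2] - a.positions_um[1, :2], [0.5, 0.3], atol=1e-12
            )
            np.testing.assert_allclose(b.positions_um[0], a.positions_um[0])

    def test_sinusoid_amplitude_bound(self):
        amp = 0.4
        tracks = simulate_tracks(
            MotionSpec(seed=12, n_frames=2, model="immobile", D=0.0),
            50,
            start_region=(np.array([4.0, 4.0, 0.5]), np.array([3.0, 3.0, 0.1])),
        )
        d = SinusoidalDeformation((amp, amp), wavelength_um=5.0)
        affines = [(np.eye(2), np.zeros(2))] * 2
        moved = apply_global_motion_tracks(tracks, affines, [d, d])
        disp = np.linalg.norm(
            np.stack([m.positions_um[1, :2] - t.positions_um[1, :2] for m, t in zip(moved, tracks)]),
            axis=1,
        )
        assert disp.max() <= amp * np.sqrt(2) + 1e-9
        # the analytic field evaluated at track positions matches exactly
        expect = d(np.stack([t.positions_um[1, :2] for t in tracks]))
        got = np.stack([m.positions_um[1, :2] - t.positions_um[1, :2] for m, t in zip(moved, tracks)])
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_noninvertible_affine_rejected(self):
        tracks = simulate_tracks(MotionSpec(seed=13, n_frames=2), 1)
        bad = [(np.eye(2), np.zeros(2)), (np.zeros((2, 2)), np.zeros(2))]
        with pytest.raises(ValueError):
            apply_global_motion_tracks(tracks, bad)

    def test_stack_identity_resample_exact(self):
        tracks = simulate_tracks(MotionSpec(seed=14), 3)
        cfg = SceneConfig(shape_tzyx=(2, 3, 48, 48))
        stack, _ = render_timelapse(tracks, cfg)
        affines = [(np.eye(2), np.zeros(2))] * 2
        out = apply_global_motion_stack(stack, affines)
        np.testing.assert_array_equal(out.data, stack.data)


class TestDnaScene:
    def test_single_focus_fraction(self):
        stack, gt = make_dna_scene([0.5], noise_sigma=0.0, seed=1)
        dapi = stack.frame(0, 0)
        m = gt.focus_masks == 1
        ratio = dapi[m].sum() / dapi[gt.nucleus_mask].sum()
        assert ratio == pytest.approx(0.5, abs=0.005)

    def test_equal_fractions_symmetric(self):
        fr = [0.05] * 10
        stack, gt = make_dna_scene(fr, noise_sigma=0.0, seed=2)
        dapi = stack.frame(0, 0)
        total = dapi[gt.nucleus_mask].sum()
        ratios = [dapi[gt.focus_masks == i + 1].sum() / total for i in range(10)]
        assert max(ratios) / min(ratios) < 1.01

    def test_fractions_must_sum_below_one(self):
        with pytest.raises(ValueError):
            make_dna_scene([0.6, 0.5])
        with pytest.raises(ValueError):
            make_dna_scene([-0.1])
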