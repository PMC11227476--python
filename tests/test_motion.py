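"""MSD computation, model fits, motion properties and rank-sum comparison."""

import itertools

import numpy as np
import pytest

from chromomotion.containers import Trajectory
from chromomotion.motion import (
    MSDCurve,
    compare_groups,
    ensemble_msd,
    fit_anomalous,
    fit_diffusion,
    motion_properties,
    msd,
    per_track_alpha,
)
from chromomotion.simulate import MotionSpec, simulate_tracks


def straight_track(v, n=12, dt=10.0, dims=3):
    t = np.arange(n) * dt
    pos = np.zeros((n, dims))
    pos[:, 0] = v * t
    return Trajectory(0, np.arange(n), pos, dt_s=dt)


class TestMSD:
    def test_stationary_track_zero_msd(self):
        tr = Trajectory(0, np.arange(6), np.ones((6, 3)), dt_s=10.0)
        c = msd(tr)
        assert np.all(c.msd_um2 == 0.0)

    def test_ballistic_closed_form(self):
        v = 0.013
        c = msd(straight_track(v))
        np.testing.assert_allclose(c.msd_um2, (v * c.lags_s) ** 2, rtol=1e-12)

    def test_pair_counts(self):
        c = msd(straight_track(0.01, n=12))
        np.testing.assert_array_equal(c.n_pairs, np.arange(11, 0, -1))

    def test_gapped_track_skips_missing_pairs(self):
        frames = np.array([0, 1, 3, 4])
        pos = np.zeros((4, 2))
        pos[:, 0] = frames  # speed 1 um/frame
        tr = Trajectory(0, frames, pos, dt_s=1.0)
        c = msd(tr)
        # lag 1: pairs (0,1),(3,4); lag 2: (1,3); lag 3: (0,3),(1,4); lag 4: (0,4)
        np.testing.assert_array_equal(c.n_pairs, [2, 1, 2, 1])
        np.testing.assert_allclose(c.msd_um2, [1.0, 4.0, 9.0, 16.0])

    def test_ensemble_is_unweighted_mean(self):
        t1 = straight_track(0.01, n=4)
        t2 = straight_track(0.03, n=8)
        ens = ensemble_msd([t1, t2])
        # lag beyond t1's span comes from t2 alone
        assert ens.msd_um2[-1] == pytest.approx((0.03 * ens.lags_s[-1]) ** 2)
        c1, c2 = msd(t1), msd(t2)
        assert ens.msd_um2[0] == pytest.approx((c1.msd_um2[0] + c2.msd_um2[0]) / 2)

    def test_brownian_ensemble_matches_6DDt(self):
        D = 5e-5
        tracks = simulate_tracks(MotionSpec(model="brownian", D=D, seed=20), 1000)
        c = ensemble_msd(tracks)
        for lag, m in zip(c.lags_s[:5], c.msd_um2[:5]):
            assert m / (6 * lag) == pytest.approx(D, rel=0.10)

    def test_time_average_matches_ensemble_average(self):
        # stationary increments: TA-MSD (averaged over tracks) equals the
        # ensemble displacement moment at every lag
        tracks = simulate_tracks(
            MotionSpec(model="anomalous", D=5e-5, alpha=0.7, seed=21), 2000
        )
        c = ensemble_msd(tracks)
        pos = np.stack([tr.positions_um for tr in tracks])
        for k in (1, 3, 5):
            ens = np.mean(np.sum((pos[:, k] - pos[:, 0]) ** 2, axis=1))
            assert abs(c.msd_um2[k - 1] - ens) / ens < 0.10

    def test_too_short_track_raises(self):
        tr = Trajectory(0, [0], [[0.0, 0.0, 0.0]], dt_s=10.0)
        with pytest.raises(ValueError):
            msd(tr)


class TestFits:
    def test_diffusion_exact_curve(self):
        D = 8.32e-5
        lags = np.arange(1, 12) * 10.0
        c = MSDCurve(lags, 6 * D * lags, np.arange(11, 0, -1), dims=3)
        assert fit_diffusion(c).D_um2_s == pytest.approx(D, rel=1e-12)

    def test_diffusion_apparent_D_on_ballistic_curve(self):
        # weighted through-origin regression on MSD = (v t)^2 has the
        # closed form apparent D = v^2 sum(w t^3) / (6 sum(w t^2))
        v = 0.01
        lags = np.arange(1, 12) * 10.0
        w = np.arange(11, 0, -1).astype(float)
        c = MSDCurve(lags, (v * lags) ** 2, w, dims=3)
        expect = v**2 * np.sum(w * lags**3) / (6 * np.sum(w * lags**2))
        assert fit_diffusion(c).D_um2_s == pytest.approx(expect, rel=1e-12)

    def test_diffusion_zero_curve(self):
        lags = np.arange(1, 5) * 10.0
        c = MSDCurve(lags, np.zeros(4), np.ones(4), dims=3)
        assert fit_diffusion(c).D_um2_s == 0.0

    def test_diffusion_negative_slope_flagged(self):
        lags = np.arange(1, 5) * 10.0
        c = MSDCurve(lags, -lags, np.ones(4), dims=3)
        f = fit_diffusion(c)
        assert f.D_um2_s == 0.0 and f.D_flag == "negative_slope"

    @pytest.mark.parametrize(
        "exponent,expected", [(2.0, 2.0), (1.0, 1.0)],
        ids=["ballistic", "brownian"],
    )
    def test_anomalous_exact_power_laws(self, exponent, expected):
        lags = np.arange(1, 12) * 10.0
        c = MSDCurve(lags, 1e-4 * lags**exponent, np.arange(11, 0, -1), dims=3)
        assert fit_anomalous(c).alpha == pytest.approx(expected, abs=1e-3)

    def test_anomalous_gamma_prefactor(self):
        lags = np.arange(1, 12) * 10.0
        c = MSDCurve(lags, 3.7e-4 * lags**0.8, np.ones(11), dims=3)
        f = fit_anomalous(c)
        assert f.gamma == pytest.approx(3.7e-4, rel=1e-9)

    def test_anomalous_drops_nonpositive_lags(self):
        lags = np.arange(1, 6) * 10.0
        vals = 1e-4 * lags.copy()
        vals[2] = 0.0
        f = fit_anomalous(MSDCurve(lags, vals, np.ones(5), dims=3))
        assert f.alpha == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(ValueError):
            fit_anomalous(MSDCurve(lags[:3], np.array([1e-4, 0, 0]), np.ones(3), dims=3))

    def test_simulated_fbm_alpha_recovery(self):
        alpha = 0.76
        tracks = simulate_tracks(
            MotionSpec(model="anomalous", D=8e-5, alpha=alpha, seed=22), 1000
        )
        f = fit_anomalous(ensemble_msd(tracks))
        assert f.alpha == pytest.approx(alpha, abs=0.05)

    @pytest.mark.parametrize("alpha", [0.48, 0.95, 1.06, 1.66])
    def test_ensemble_alpha_unbiased_over_printed_range(self, alpha):
        tracks = simulate_tracks(
            MotionSpec(model="anomalous", D=8e-5, alpha=alpha, seed=23), 1000
        )
        f = fit_anomalous(ensemble_msd(tracks))
        assert abs(f.alpha - alpha) < 0.05

    @pytest.mark.parametrize(
        "D", [2.73e-5, 3.18e-5, 3.97e-5, 4.95e-5, 7.05e-5, 7.95e-5, 13.01e-5]
    )
    def test_diffusion_recovery_over_printed_range(self, D):
        tracks = simulate_tracks(MotionSpec(model="brownian", D=D, seed=24), 1000)
        f = fit_diffusion(ensemble_msd(tracks))
        assert f.D_um2_s == pytest.approx(D, rel=0.10)

    def test_per_track_alpha_nan_for_short(self):
        good = straight_track(0.01, n=12)
        bad = Trajectory(1, [0, 1], np.zeros((2, 3)), dt_s=10.0)
        out = per_track_alpha([good, bad])
        assert out[0] == pytest.approx(2.0, abs=1e-3)
        assert np.isnan(out[1])


class TestMotionProperties:
    def test_two_points(self):
        tr = Trajectory(0, [0, 1], [[0, 0, 0], [0.3, 0, 0]], dt_s=10.0)
        p = motion_properties(tr)
        assert p.radius_of_gyration_um == pytest.approx(0.15)
        assert p.straightness == 1.0
        assert p.mean_velocity_um_s == pytest.approx(0.03)

    def test_unit_square_path(self):
        pos = [[0, 0], [1, 0], [1, 1], [0, 1]]
        tr = Trajectory(0, np.arange(4), pos, dt_s=1.0)
        p = motion_properties(tr)
        assert p.radius_of_gyration_um == pytest.approx(np.sqrt(0.5))
        assert p.distance_start_end_um == pytest.approx(1.0)
        assert p.straightness == pytest.approx(1 / 3)

    def test_l_path(self):
        tr = Trajectory(0, np.arange(3), [[0, 0], [1, 0], [1, 1]], dt_s=1.0)
        p = motion_properties(tr)
        assert p.distance_start_end_um == pytest.approx(np.sqrt(2))
        assert p.straightness == pytest.approx(np.sqrt(2) / 2)

    def test_zero_path_flagged(self):
        tr = Trajectory(0, [0, 1], np.zeros((2, 3)), dt_s=1.0)
        p = motion_properties(tr)
        assert p.straightness == 0.0 and p.flag == "zero_path"


def rank_sum_enumeration(a, b):
    """Brute-force exact two-sided rank-sum p-value (no ties)."""
    combined = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(combined)) + 1
    w_obs = ranks[: len(a)].sum()
    n = len(combined)
    mu = len(a) * (n + 1) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(1, n + 1), len(a)):
        w = sum(comb)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestCompareGroups:
    def test_identical_groups(self):
        assert compare_groups([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_fully_separated_3v3_exact(self):
        assert compare_groups([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(20):
            na, nb = rng.integers(2, 7), rng.integers(2, 7)
            a = rng.normal(size=na)
            b = rng.normal(loc=rng.normal(), size=nb)
            assert compare_groups(a, b) == pytest.approx(rank_sum_enumeration(a, b), abs=1e-9)

    def test_large_shift_significant(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        assert compare_groups(a, b) < 1e-10

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])
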