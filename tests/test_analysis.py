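"""Time-average statistics: closed-form cases, invariances, MFPT, velocities."""

import numpy as np
import pytest

from cargodyn import (
    SimConfig,
    Trajectory,
    anomalous_exponent,
    detrend,
    dominant_peak,
    make_lag_grid,
    mfpt,
    simulate,
    tamd,
    tamsd,
    tavar,
    velocity_distribution,
)
from cargodyn.analysis import LagGrid
from cargodyn.io import make_fixture
from cargodyn.kinetics import GammaMixture
from cargodyn.scenarios import EnsembleRunConfig, ensemble_trajectories


def _ballistic(v=1.0, duration=1.0, dt=1e-3):
    t = np.arange(int(round(duration / dt)) + 1) * dt
    return Trajectory(times=t, x=v * t, y=np.zeros_like(t))


def _grid(traj, lo, hi, ppd=10):
    return make_lag_grid(traj, lo, hi, ppd)


class TestTamsdTamdTavar:
    def test_ballistic_tamsd_closed_form(self):
        tr = _ballistic(v=2.0)
        grid = _grid(tr, 1e-2, 0.3)
        curve = tamsd(tr, grid)
        np.testing.assert_allclose(curve.values, (2.0 * curve.lags) ** 2, rtol=1e-10)

    def test_stationary_point_gives_zero(self):
        t = np.arange(101) * 0.01
        tr = Trajectory(times=t, x=np.full_like(t, 3.0), y=np.full_like(t, -1.0))
        grid = _grid(tr, 0.05, 0.5)
        assert np.all(tamsd(tr, grid).values == 0.0)
        assert np.all(tavar(tr, grid).values == 0.0)

    def test_ballistic_tamd_vector(self):
        tr = _ballistic(v=1.5)
        grid = _grid(tr, 1e-2, 0.3)
        curve = tamd(tr, grid)
        np.testing.assert_allclose(curve.components["x"], 1.5 * curve.lags, rtol=1e-10)
        np.testing.assert_allclose(curve.components["y"], 0.0, atol=1e-12)

    def test_ballistic_tavar_is_zero(self):
        tr = _ballistic()
        grid = _grid(tr, 1e-2, 0.3)
        np.testing.assert_allclose(tavar(tr, grid).values, 0.0, atol=1e-15)

    def test_brownian_tamsd_slope(self):
        trajs = [make_fixture("brownian", {"duration": 4.0}, seed=s) for s in range(6)]
        curves = []
        for tr in trajs:
            grid = _grid(tr, 1e-3, 0.4, 8)
            curves.append(tamsd(tr, grid).values)
            lags = grid.lags
        slope = np.polyfit(np.log(lags), np.log(np.mean(curves, axis=0)), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_fgn_path_tavar_slope(self):
        trajs = [make_fixture("fgn", {"duration": 4.0, "hurst": 0.35}, seed=s)
                 for s in range(6)]
        curves = []
        for tr in trajs:
            grid = _grid(tr, 1e-3, 0.4, 8)
            curves.append(tavar(tr, grid).values)
            lags = grid.lags
        slope = np.polyfit(np.log(lags), np.log(np.mean(curves, axis=0)), 1)[0]
        assert slope == pytest.approx(0.7, abs=0.05)

    def test_tavar_never_exceeds_tamsd(self):
        tr = simulate(SimConfig(duration=4.0, dt=1e-4, seed=5))
        grid = _grid(tr, 1e-3, 0.4)
        assert np.all(tavar(tr, grid).values <= tamsd(tr, grid).values + 1e-15)

    def test_tavar_equals_per_lag_detrended_tamsd(self):
        # TAMSD - TAMD^2 is exactly the variance of the window displacement,
        # i.e. the TAMSD with the mean displacement removed at each lag
        tr = simulate(SimConfig(duration=4.0, dt=1e-4, seed=6))
        grid = _grid(tr, 1e-3, 0.4)
        a = tavar(tr, grid).values
        b = tamsd(tr, grid, detrend_per_lag=True).values
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_global_detrend_approximates_tavar(self):
        # subtracting the global mean increment (path pinned at both ends)
        # reproduces TAVAR up to O((lag/T)^2) boundary terms
        tr = simulate(SimConfig(duration=8.0, dt=1e-4, seed=6))
        grid = _grid(tr, 1e-3, 0.2)
        a = tavar(tr, grid).values
        b = tamsd(detrend(tr), grid).values
        np.testing.assert_allclose(b, a, rtol=0.05)

    def test_translation_and_rotation_invariance(self):
        tr = simulate(SimConfig(duration=2.0, dt=1e-4, seed=2))
        grid = _grid(tr, 1e-3, 0.2)
        shifted = Trajectory(times=tr.times, x=tr.x + 5.0, y=tr.y - 3.0)
        th = 0.7
        rot = Trajectory(
            times=tr.times,
            x=np.cos(th) * tr.x - np.sin(th) * tr.y,
            y=np.sin(th) * tr.x + np.cos(th) * tr.y,
        )
        np.testing.assert_allclose(tamsd(tr, grid).values, tamsd(shifted, grid).values,
                                   rtol=1e-10)
        np.testing.assert_allclose(tavar(tr, grid).values, tavar(shifted, grid).values,
                                   rtol=1e-10)
        np.testing.assert_allclose(tamsd(tr, grid).values, tamsd(rot, grid).values,
                                   rtol=1e-10)

    def test_run_rest_tamd_grows_linearly(self):
        cfg = EnsembleRunConfig(residence=GammaMixture(mu=1.4, tau_d=1.0),
                                n_traj=20, duration=100.0, seed=3)
        curves = []
        for tr in ensemble_trajectories(cfg):
            grid = _grid(tr, 0.5, 10.0, 8)
            curves.append(tamd(tr, grid).values)
            lags = grid.lags
        slope = np.polyfit(np.log(lags), np.log(np.mean(curves, axis=0)), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)


class TestAnomalousExponent:
    @pytest.mark.parametrize("alpha", [0.7, 1.6, 2.0])
    def test_exact_power_law_recovered(self, alpha):
        lags = np.geomspace(1e-3, 1.0, 40)
        curve_vals = 0.37 * lags**alpha
        from cargodyn.analysis import SummaryCurve

        curve = SummaryCurve(lags=lags, values=curve_vals, statistic="tavar")
        assert anomalous_exponent(curve, (1e-3, 1.0)) == pytest.approx(alpha, rel=1e-12)
        assert curve.fit_window == (1e-3, 1.0)

    def test_too_few_lags_rejected(self):
        from cargodyn.analysis import SummaryCurve

        curve = SummaryCurve(lags=np.array([0.1, 0.2, 0.4]),
                             values=np.array([1.0, 2.0, 4.0]), statistic="tamsd")
        with pytest.raises(ValueError):
            anomalous_exponent(curve, (0.05, 0.5))


class TestLagGrid:
    def test_rejects_non_multiples(self):
        with pytest.raises(ValueError):
            LagGrid(lags=np.array([0.0015]), delta=1e-3)

    def test_rejects_lag_beyond_duration(self):
        tr = _ballistic(duration=1.0)
        with pytest.raises(ValueError):
            make_lag_grid(tr, 0.1, 2.0)


class TestMfpt:
    def test_ballistic_closed_form(self):
        tr = _ballistic(v=1.0, duration=2.0, dt=1e-3)
        L = np.array([0.1, 0.5, 1.0])
        curve = mfpt(tr, L)
        np.testing.assert_allclose(curve.mfpt, L, rtol=0.02)

    def test_nondecreasing_in_distance(self):
        tr = simulate(SimConfig(duration=4.0, dt=1e-4, seed=8))
        L = np.geomspace(0.01, 1.0, 10)
        curve = mfpt(tr, L, start_stride=50)
        m = curve.mfpt[~np.isnan(curve.mfpt)]
        assert np.all(np.diff(m) >= 0)

    def test_unreached_distance_flagged_missing(self):
        tr = _ballistic(v=1.0, duration=1.0, dt=1e-3)
        curve = mfpt(tr, np.array([0.5, 50.0]))
        assert np.isfinite(curve.mfpt[0])
        assert np.isnan(curve.mfpt[1]) and curve.counts[1] == 0

    def test_brownian_scaling(self):
        # MFPT(L) ~ L^2 for Brownian paths (Monte-Carlo over many paths)
        ratios = []
        for s in range(30):
            tr = make_fixture("brownian", {"duration": 8.0, "dt": 1e-3}, seed=s)
            c = mfpt(tr, np.array([0.02, 0.04]), start_stride=10)
            if np.all(np.isfinite(c.mfpt)):
                ratios.append(c.mfpt[1] / c.mfpt[0])
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.25)


class TestVelocityDistribution:
    def test_constant_velocity_single_bin(self):
        tr = _ballistic(v=1.0, duration=2.0, dt=1e-3)
        hist = velocity_distribution(tr, delta_min=1e-2, bin_width=0.05)
        nonzero = hist.centers[hist.counts > 0]
        # all mass in the (at most two, edge-straddling) bins around 1.0
        assert nonzero.size <= 2
        np.testing.assert_allclose(nonzero, 1.0, atol=0.05)

    def test_two_segment_mixture_against_enumeration(self):
        # half at 0.5 um/s then half at 1.0; compare with brute-force pooling
        dt, n_half = 1e-3, 1000
        t = np.arange(2 * n_half + 1) * dt
        x = np.concatenate([0.5 * t[: n_half + 1],
                            0.5 * t[n_half] + 1.0 * (t[n_half + 1:] - t[n_half])])
        tr = Trajectory(times=t, x=x, y=np.zeros_like(t))
        hist = velocity_distribution(tr, delta_min=1e-2, bin_width=0.02)
        # brute force: same lag grid, all start points, plain loops
        grid = make_lag_grid(tr, 1e-2, 0.1 * tr.duration, 20)
        speeds = []
        for n in grid.indices:
            for i in range(len(x) - n):
                speeds.append(abs(x[i + n] - x[i]) / (n * dt))
        ref, _ = np.histogram(speeds, bins=hist.edges)
        np.testing.assert_array_equal(hist.counts, ref)
        peaks = hist.centers[(hist.counts > 0.5 * hist.counts.max())]
        assert peaks.min() < 0.55 and peaks.max() > 0.95

    def test_all_rest_mass_at_zero(self):
        t = np.arange(2001) * 1e-3
        tr = Trajectory(times=t, x=np.zeros_like(t), y=np.zeros_like(t))
        hist = velocity_distribution(tr, delta_min=1e-2)
        assert hist.counts[0] == hist.counts.sum()

    def test_short_trajectory_rejected(self):
        tr = _ballistic(duration=0.05, dt=1e-3)
        with pytest.raises(ValueError):
            velocity_distribution(tr, delta_min=1e-2)

    def test_dominant_peak_finds_interior_maximum(self):
        from cargodyn.analysis import VelocityHistogram

        edges = np.arange(0.0, 2.0, 0.05)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = (1000 / (centers + 0.1)).astype(int)  # falling background
        counts[np.abs(centers - 1.0) < 0.1] += 800     # hump at 1.0
        hist = VelocityHistogram(edges=edges, counts=counts, lag_range=(0.01, 1.0))
        assert dominant_peak(hist, min_speed=0.2) == pytest.approx(1.0, abs=0.08)
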