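"""Evaluation metrics and ensemble summaries."""

import numpy as np
import pytest

import rateguard as rg
from rateguard.config import KineticConfig
from rateguard.evaluation import (change_detection_delay, cv, interior_max,
                                  interior_mean, mape, rmse, screen_p,
                                  timepoint_cv)
from rateguard.rates import RateSeries
from rateguard.simulate import TrueTrajectory


def stub_trajectory(t, mu, cfg=None):
    """Minimal true trajectory with a prescribed mu(t) profile."""
    t = np.asarray(t, dtype=float)
    mu = np.asarray(mu, dtype=float)
    cfg = cfg or KineticConfig(model="noncompetitive", t_end=float(t[-1]),
                               t_induction=min(10.0, float(t[-1]) / 2))
    ones = np.ones_like(t)
    return TrueTrajectory(t=t, x=ones, S=ones, V=ones, uf=np.zeros_like(t),
                          inhibitor=np.zeros_like(t), mu_true=mu,
                          qS_true=mu / cfg.Y_xs, config=cfg)


class TestCV:
    def test_constant_sample_is_zero(self):
        assert cv([3.0, 3.0, 3.0]) == 0.0

    def test_sd_over_mean_identity(self):
        # mean 20, sd 1.5 -> 7.5% (the biomass-precision arithmetic)
        x = 1.5 / np.sqrt(2.0)
        assert cv([20.0 - x, 20.0 + x]) == pytest.approx(7.5, abs=1e-12)

    def test_hand_computed_two_point_sample(self):
        assert cv([1.0, 3.0]) == pytest.approx(np.sqrt(2.0) / 2.0 * 100.0)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            cv([1.0])
        with pytest.raises(ValueError):
            cv([-1.0, 1.0])


class TestErrorMetrics:
    def test_perfect_estimate_scores_zero(self, monod_traj):
        t = np.linspace(0.5, 19.5, 20)
        series = RateSeries(t=t, value=monod_traj.mu_at(t), method="spline",
                            p=0.4)
        assert rmse(series, monod_traj) == 0.0
        assert mape(series, monod_traj) == 0.0

    def test_rmse_of_symmetric_errors(self):
        truth = stub_trajectory([0.0, 1.0, 2.0], [0.2, 0.2, 0.2])
        series = RateSeries(t=[0.5, 1.5], value=[0.3, 0.1], method="stepwise")
        assert rmse(series, truth) == pytest.approx(0.1)

    def test_constant_estimate_against_constant_truth(self):
        truth = stub_trajectory([0.0, 2.0], [0.5, 0.5])
        series = RateSeries(t=[1.0], value=[0.75], method="stepwise")
        assert rmse(series, truth) == pytest.approx(0.25)

    def test_mape_single_point(self):
        truth = stub_trajectory([0.0, 2.0], [2.0, 2.0])
        series = RateSeries(t=[1.0], value=[1.5], method="stepwise")
        assert mape(series, truth) == pytest.approx(25.0)

    def test_mape_uniform_overestimate(self):
        truth = stub_trajectory([0.0, 5.0], [0.4, 0.4])
        t = np.linspace(0.5, 4.5, 9)
        series = RateSeries(t=t, value=np.full(9, 0.44), method="spline",
                            p=0.4)
        assert mape(series, truth) == pytest.approx(10.0)


class TestTimepointCV:
    def test_identical_replicates_have_zero_cv(self):
        s = RateSeries(t=np.arange(5.0), value=np.full(5, 0.2),
                       method="stepwise")
        out = timepoint_cv([s, s, s])
        assert np.allclose(out.value, 0.0)

    def test_mismatched_grids_rejected(self):
        a = RateSeries(t=np.arange(5.0), value=np.ones(5), method="stepwise")
        b = RateSeries(t=np.arange(5.0) + 0.5, value=np.ones(5),
                       method="stepwise")
        with pytest.raises(ValueError, match="share timestamps"):
            timepoint_cv([a, b])

    def test_interior_summaries_drop_boundary(self):
        s = RateSeries(t=np.arange(5.0), value=[9.0, 1.0, 2.0, 3.0, 9.0],
                       method="stepwise")
        assert interior_mean(s) == pytest.approx(2.0)
        assert interior_max(s) == pytest.approx(3.0)


class TestScreenP:
    def test_zero_noise_prefers_no_smoothing(self, monod_cfg, monod_traj):
        # on noise-free data the error grows monotonically as p -> 0
        noise = rg.NoiseSpec(cv_biomass=0, cv_substrate=0, cv_volume=0,
                             cv_feed=0, seed=0)
        obs = rg.sample_and_corrupt(monod_traj, 1.0, noise)
        grid = np.round(np.arange(0.1, 1.01, 0.1), 1)
        errs = [rmse(rg.spline_mu(obs, p), monod_traj) for p in grid]
        assert np.all(np.diff(errs) <= 1e-12)

    def test_small_screen_structure(self, monod_cfg, monod_traj):
        grid = screen_p(monod_cfg, intervals=(1.0,), noise_levels=(7.5,),
                        p_grid=(0.2, 0.4, 0.8), n=10, base_seed=4,
                        traj=monod_traj)
        assert len(grid.table) == 3
        assert grid.table["argmin_p"].nunique() == 1
        assert "global_argmin_p" in grid.table.attrs


class TestChangeDetection:
    def test_perfect_series_has_zero_delay(self, nc_traj):
        t = nc_traj.t[:: 100]
        series = RateSeries(t=t, value=nc_traj.mu_at(t), method="spline",
                            p=0.4)
        assert abs(change_detection_delay(series, nc_traj)) < 0.5

    def test_shifted_series_reports_the_shift(self):
        # mu crosses the 15% threshold at 12.5 h; a +1 h shift -> +8%
        t = np.linspace(0.0, 20.0, 201)
        mu = np.where(t < 5.0, 0.2, 0.2 - 0.004 * (t - 5.0))
        truth = stub_trajectory(t, mu,
                                KineticConfig(model="noncompetitive",
                                              t_end=20.0, t_induction=5.0))
        shifted = RateSeries(t=t + 1.0, value=mu, method="stepwise")
        delay = change_detection_delay(shifted, truth)
        assert delay == pytest.approx(8.0, abs=0.3)

    def test_never_crossing_series_is_not_detected(self, nc_traj):
        t = np.linspace(0.0, 24.0, 25)
        series = RateSeries(t=t, value=np.full_like(t, 0.19),
                            method="stepwise")
        assert np.isnan(change_detection_delay(series, nc_traj))
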