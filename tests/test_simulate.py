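"""Simulator: kinetic law, ODE solution, noise corruption, ensembles."""

import numpy as np
import pytest

import rateguard as rg
from rateguard.config import KineticConfig


class TestGrowthRateLaw:
    def test_monod_saturates_at_mu_max(self, monod_cfg):
        assert rg.growth_rate_law(1e9, 0.0, monod_cfg) == pytest.approx(
            monod_cfg.mu_max, rel=1e-6)

    def test_half_saturation_identity(self, monod_cfg):
        mu = rg.growth_rate_law(monod_cfg.K_s, 0.0, monod_cfg)
        assert mu == pytest.approx(monod_cfg.mu_max / 2.0)

    def test_no_inhibition_before_induction(self, nc_cfg, monod_cfg):
        S = 1.234
        before = rg.growth_rate_law(S, nc_cfg.t_induction - 0.1, nc_cfg,
                                    inhibitor=0.7)
        assert before == pytest.approx(rg.growth_rate_law(S, 0.0, monod_cfg))
        after = rg.growth_rate_law(S, nc_cfg.t_induction + 0.1, nc_cfg,
                                   inhibitor=0.7)
        assert after < before

    def test_negative_substrate_rejected(self, monod_cfg):
        with pytest.raises(ValueError, match="negative substrate"):
            rg.growth_rate_law(-0.1, 0.0, monod_cfg)


class TestSimulate:
    def test_batch_grows_exponentially_at_mu_max(self):
        # no feed, substrate far above K_s: log-linear slope == mu_max +- 1%
        cfg = KineticConfig(model="monod", feed_scale=0.0, S0=20.0, x0=0.5,
                            t_end=2.0)
        traj = rg.simulate(cfg)
        slope = np.polyfit(traj.t, np.log(traj.total_biomass), 1)[0]
        assert slope == pytest.approx(cfg.mu_max, rel=0.01)

    @pytest.mark.parametrize("which", ["monod", "noncompetitive"])
    def test_mass_balance_conservation(self, which, monod_traj, nc_traj):
        traj = monod_traj if which == "monod" else nc_traj
        assert traj.mass_balance_residual() < 1e-6

    def test_monod_mu_nearly_constant_during_fed_batch(self, monod_traj):
        mu = monod_traj.mu_true
        assert (mu.max() - mu.min()) / mu.mean() < 0.10

    def test_noncompetitive_mu_declines_after_induction(self, nc_traj, nc_cfg):
        post = nc_traj.mu_true[nc_traj.t >= nc_cfg.t_induction]
        plateau = nc_traj.mu_true[nc_traj.t < nc_cfg.t_induction].mean()
        assert np.all(np.diff(post) <= 1e-6)  # monotone up to solver tolerance
        assert post[-1] < 0.85 * plateau  # at least a 15% drop

    def test_batch_depletion_self_limits(self):
        # Monod kinetics shut growth down as S -> 0: no negative substrate
        cfg = KineticConfig(model="monod", feed_scale=0.0, S0=0.5, x0=2.0,
                            t_end=8.0)
        traj = rg.simulate(cfg)
        assert np.all(traj.S >= 0)
        assert traj.mu_true[-1] < 0.02 * cfg.mu_max

    def test_volume_nondecreasing(self, monod_traj, nc_traj):
        for traj in (monod_traj, nc_traj):
            assert np.all(np.diff(traj.V) >= 0)


class TestSampleAndCorrupt:
    def test_zero_noise_recovers_truth(self, monod_traj, noise_free):
        obs = rg.sample_and_corrupt(monod_traj, 2.0, noise_free)
        idx = np.searchsorted(monod_traj.t, obs.t_sample - 1e-12)
        assert np.allclose(obs.x_obs, monod_traj.x[idx], rtol=1e-12)
        assert np.allclose(obs.V_obs, monod_traj.V[idx], rtol=1e-12)
        assert np.allclose(obs.uf_obs, monod_traj.uf[idx], rtol=1e-12)

    def test_biomass_scatter_matches_cv(self, monod_traj):
        # 7.5% CV at ~20 g/L biomass means roughly +-1.5 g/L scatter
        noise = rg.NoiseSpec(cv_biomass=7.5, seed=42)
        ens = rg.make_ensemble(monod_traj.config, 2.0, noise, 4000,
                               traj=monod_traj)
        x = np.array([o.x_obs for o in ens])
        true_x = monod_traj.x[np.searchsorted(monod_traj.t,
                                              ens[0].t_sample - 1e-12)]
        j = int(np.argmin(np.abs(true_x - 20.0)))
        sd = x[:, j].std(ddof=1)
        assert sd == pytest.approx(0.075 * true_x[j], rel=0.06)

    def test_seed_determinism(self, monod_traj):
        noise = rg.NoiseSpec(cv_biomass=10.0, seed=7)
        a = rg.sample_and_corrupt(monod_traj, 1.0, noise)
        b = rg.sample_and_corrupt(monod_traj, 1.0, noise)
        assert np.array_equal(a.x_obs, b.x_obs)
        assert np.array_equal(a.S_obs, b.S_obs)
        assert np.array_equal(a.uf_obs, b.uf_obs)

    def test_interval_too_coarse_rejected(self, monod_traj, noise_free):
        with pytest.raises(ValueError, match="fewer than 3"):
            rg.sample_and_corrupt(monod_traj, 11.0, noise_free)


class TestMakeEnsemble:
    def test_replicates_share_grid_and_ids(self, monod_cfg, monod_traj):
        ens = rg.make_ensemble(monod_cfg, 2.0, rg.NoiseSpec(seed=1), 5,
                               traj=monod_traj)
        assert len(ens) == 5
        assert [o.replicate_id for o in ens] == list(range(5))
        for o in ens[1:]:
            assert np.array_equal(o.t_sample, ens[0].t_sample)

    def test_single_replicate_equals_sample_and_corrupt(self, monod_traj):
        noise = rg.NoiseSpec(cv_biomass=5.0, seed=11)
        ens = rg.make_ensemble(monod_traj.config, 1.0, noise, 1,
                               traj=monod_traj)
        direct = rg.sample_and_corrupt(monod_traj, 1.0, noise)
        assert np.array_equal(ens[0].x_obs, direct.x_obs)

    def test_ensemble_mean_is_unbiased(self, monod_traj):
        # CLT bound: each variable's ensemble mean within 4 standard errors
        n = 10_000
        noise = rg.NoiseSpec(cv_biomass=12.5, seed=3)
        ens = rg.make_ensemble(monod_traj.config, 4.0, noise, n,
                               traj=monod_traj)
        idx = np.searchsorted(monod_traj.t, ens[0].t_sample - 1e-12)
        for attr, true in (("x_obs", monod_traj.x[idx]),
                           ("S_obs", monod_traj.S[idx]),
                           ("V_obs", monod_traj.V[idx])):
            vals = np.array([getattr(o, attr) for o in ens])
            se = vals.std(axis=0, ddof=1) / np.sqrt(n)
            assert np.all(np.abs(vals.mean(axis=0) - true) < 4 * se + 1e-12)

    def test_ensembles_identical_under_same_seed(self, monod_cfg, monod_traj):
        noise = rg.NoiseSpec(cv_biomass=7.5, seed=99)
        a = rg.make_ensemble(monod_cfg, 2.0, noise, 3, traj=monod_traj)
        b = rg.make_ensemble(monod_cfg, 2.0, noise, 3, traj=monod_traj)
        for oa, ob in zip(a, b):
            assert np.array_equal(oa.x_obs, ob.x_obs)
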