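"""The census-step projection, kernel resampling and long-run simulation."""

import numpy as np
import pandas as pd
import pytest

import warblerpop as wp
from warblerpop.projection import PopulationState, stack_state
from warblerpop.rates import CHANNELS

from conftest import constant_kernel, toy_kernel_and_config, toy_step_oracle, zero_slope_specs


def small_state(cfg, nd=100.0, nh=50.0, nu=15.0):
    d = np.full(cfg.n_dom, nd / cfg.n_dom)
    h = np.full(cfg.n_sub, nh / cfg.n_sub)
    u = np.full(cfg.n_sub, nu / cfg.n_sub)
    return PopulationState(d=d, h=h, u=u)


class TestProjectStep:
    def test_all_rates_zero_gives_empty_population(self):
        kernel = constant_kernel({ch: -800.0 for ch in CHANNELS},
                                 slopes=zero_slope_specs(help_intercept=-800.0))
        cfg = wp.ModelConfig()
        nxt, _ = wp.project_step(small_state(cfg), kernel,
                                 kernel.intercept_vector(0), cfg)
        assert nxt.total == 0.0

    def test_certain_unhelped_reproduction_with_no_recruitment_to_helpers(self):
        """R_d(q=0)=1, f=0, everything else 0: newborns land only in u at
        age 0.5 and number exactly the dominants."""
        kernel = constant_kernel(
            {"S_d": -800.0, "S_h": -800.0, "S_u": -800.0,
             "R_d": 800.0, "R_h": -800.0, "f": -800.0},
            slopes=zero_slope_specs(help_intercept=-800.0))
        cfg = wp.ModelConfig()
        state = small_state(cfg, nd=80.0, nh=30.0, nu=10.0)
        nxt, _ = wp.project_step(state, kernel, kernel.intercept_vector(0), cfg)
        assert nxt.h.sum() == 0.0
        assert nxt.d.sum() == 0.0
        assert nxt.u[0] == pytest.approx(80.0, abs=1e-12)
        assert nxt.u[1:].sum() == 0.0

    def test_single_step_matches_independent_scalar_oracle(self):
        kernel, cfg, pars = toy_kernel_and_config()
        d = [2.0, 1.5]
        h = [1.0, 0.8, 0.5]
        u = [0.6, 0.3, 0.2]
        state = PopulationState(d=np.array(d), h=np.array(h), u=np.array(u))
        nxt, _ = wp.project_step(state, kernel, kernel.intercept_vector(0), cfg)
        nd, nh, nu = toy_step_oracle(d, h, u, pars, cfg.termax, cfg.beta, 10.0, 4.0)
        np.testing.assert_allclose(nxt.d, nd, atol=1e-12)
        np.testing.assert_allclose(nxt.h, nh, atol=1e-12)
        np.testing.assert_allclose(nxt.u, nu, atol=1e-12)

    def test_no_flow_between_subordinate_tactics(self, default_kernel):
        """Helpers never become non-helpers: with reproduction switched off
        and only helpers present, the non-helper vector stays empty."""
        kernel = constant_kernel(
            {"S_d": 2.0, "S_h": 2.0, "S_u": 2.0,
             "R_d": -800.0, "R_h": -800.0, "f": 0.0},
            slopes=zero_slope_specs())
        cfg = wp.ModelConfig()
        state = small_state(cfg, nd=100.0, nh=200.0, nu=0.0)
        for _ in range(5):
            state, _ = wp.project_step(state, kernel, kernel.intercept_vector(0), cfg)
        assert state.u.sum() == 0.0
        assert state.h.sum() > 0.0

    def test_realized_matrix_reproduces_the_step(self, default_kernel):
        cfg = wp.ModelConfig()
        state = small_state(cfg)
        intercepts = default_kernel.intercept_vector(5)
        K = wp.build_projection_matrix(state, default_kernel, intercepts, cfg)
        nxt, _ = wp.project_step(state, default_kernel, intercepts, cfg)
        np.testing.assert_allclose(K @ stack_state(state), stack_state(nxt),
                                   rtol=0, atol=1e-10)

    def test_mismatched_grid_rejected(self, default_kernel):
        cfg = wp.ModelConfig()
        bad = PopulationState(d=np.ones(3), h=np.ones(3), u=np.ones(3))
        with pytest.raises(ValueError, match="dimensions"):
            wp.project_step(bad, default_kernel,
                            default_kernel.intercept_vector(0), cfg)


class TestDrawSeason:
    def test_single_season_kernel_is_deterministic(self):
        kernel = constant_kernel({ch: 0.3 for ch in CHANNELS})
        rng = np.random.default_rng(0)
        labels = {wp.draw_season(kernel, rng)[0] for _ in range(50)}
        assert labels == {0}

    def test_uniform_frequencies_over_many_draws(self, default_kernel):
        rng = np.random.default_rng(1)
        n = 10_000
        counts = np.zeros(default_kernel.n_seasons)
        for _ in range(n):
            label, _ = wp.draw_season(default_kernel, rng)
            counts[label] += 1
        p = 1.0 / default_kernel.n_seasons
        se = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 3.5 * se)

    def test_joint_draws_preserve_within_season_covariance(self, default_kernel):
        rng = np.random.default_rng(2)
        draws = np.array([wp.draw_season(default_kernel, rng)[1].to_numpy()
                          for _ in range(20_000)])
        sample_cov = np.cov(draws.T)
        kernel_cov = np.cov(default_kernel.intercepts.to_numpy().T, ddof=0)
        # resampling with replacement converges to the population (ddof=0) covariance
        np.testing.assert_allclose(sample_cov, kernel_cov, atol=0.02)


class TestSimulate:
    def test_reproducible_given_seed(self, default_kernel, short_config):
        a = wp.simulate(default_kernel, short_config, rng=11)
        b = wp.simulate(default_kernel, short_config, rng=11)
        pd.testing.assert_frame_equal(a.summary, b.summary)
        np.testing.assert_array_equal(a.states_h, b.states_h)

    def test_deterministic_kernel_converges_to_fixed_point(self, default_kernel):
        kernel = constant_kernel(default_kernel.mean_intercepts().to_dict())
        cfg = wp.ModelConfig(horizon=900, burn_in=800)
        res = wp.simulate(kernel, cfg, rng=0)
        post_N = res.post_burn_in["N"].to_numpy()
        assert np.ptp(post_N) < 1e-6
        assert res.mean_population_size == pytest.approx(post_N[-1], abs=1e-6)

    def test_extinction_truncates_with_time(self):
        kernel = constant_kernel({ch: -800.0 for ch in CHANNELS},
                                 slopes=zero_slope_specs(help_intercept=-800.0))
        cfg = wp.ModelConfig(horizon=100, burn_in=50)
        res = wp.simulate(kernel, cfg, rng=0)
        assert res.extinct_at is not None and res.extinct_at <= 3
        assert len(res.summary) == res.extinct_at

    def test_doubling_capacity_scales_dominant_total(self, default_kernel):
        import copy
        cfg1 = wp.ModelConfig(horizon=600, burn_in=400)
        cfg2 = wp.ModelConfig(horizon=600, burn_in=400, termax=2 * 111.2)
        k2 = copy.deepcopy(default_kernel)
        k2.standardisation = (2 * 170.0, 2 * 20.0)   # rescale density dependence too
        r1 = wp.simulate(default_kernel, cfg1, rng=3)
        r2 = wp.simulate(k2, cfg2, rng=3)
        assert r2.stage_means()["d"] == pytest.approx(2 * r1.stage_means()["d"], rel=1e-6)


class TestStageAgeDistribution:
    def test_distributions_sum_to_one_and_match_tabulation(self, default_kernel):
        cfg = wp.ModelConfig(horizon=600, burn_in=400)
        res = wp.simulate(default_kernel, cfg, rng=5)
        dist = wp.stage_age_distribution(res)
        for stage, arr in (("d", res.states_d), ("h", res.states_h), ("u", res.states_u)):
            assert dist[stage]["mean"].sum() == pytest.approx(1.0, abs=1e-12)
            norm = arr / arr.sum(axis=1, keepdims=True)
            direct = norm.mean(axis=0)
            np.testing.assert_allclose(dist[stage]["mean"], direct / direct.sum(),
                                       atol=1e-12)

    def test_single_age_population_is_point_mass(self, default_kernel):
        cfg = wp.ModelConfig(horizon=3, burn_in=1)
        res = wp.simulate(default_kernel, cfg, rng=0)
        res.states_h[:] = 0.0
        res.states_h[:, 4] = 7.0
        dist = wp.stage_age_distribution(res)
        assert dist["h"]["mean"].iloc[4] == pytest.approx(1.0)

    def test_nonhelpers_younger_than_helpers(self, default_kernel):
        """Faster promotion drains old non-helpers, so their stationary age
        distribution is the youngest."""
        cfg = wp.ModelConfig(horizon=1200, burn_in=600)
        res = wp.simulate(default_kernel, cfg, rng=8)
        dist = wp.stage_age_distribution(res)
        f_u = wp.mass_below_age(dist["u"], 2.0)
        f_h = wp.mass_below_age(dist["h"], 2.0)
        f_d = wp.mass_below_age(dist["d"], 2.0)
        assert f_u > f_h > f_d
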