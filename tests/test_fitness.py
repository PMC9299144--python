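"""Lifetime reproductive success: cohorts, Markov rewards, reproductive values."""

import numpy as np
import pytest

import warblerpop as wp
from warblerpop.fitness import RewardChain, frozen_environment, _left_eigvec
from warblerpop.rates import CHANNELS

from conftest import constant_kernel


def geometric_closed_forms(s: float, p: float):
    """Independent closed forms for LRS of a one-state chain.

    Lifetime T (number of censuses alive) is geometric on {1, 2, ...}
    with continuation probability ``s``; LRS is a Bernoulli(``p``) sum
    over T. Moments follow from the factorial moments of T and the
    compound-sum formulas.
    """
    q = 1.0 - s
    ET = 1.0 / q
    ET2f = 2.0 * s / q**2                 # E[T(T-1)]
    ET3f = 6.0 * s**2 / q**3              # E[T(T-1)(T-2)]
    mean = p * ET
    ES2 = p * ET + p**2 * ET2f            # E[S^2] for Bernoulli rewards
    var = ES2 - mean**2
    ES3 = p * ET + 3 * p**2 * ET2f + p**3 * ET3f
    m3 = ES3 - 3 * mean * ES2 + 2 * mean**3
    return mean, var, m3 / var**1.5


class TestLrsMoments:
    def test_one_state_chain_matches_closed_forms(self):
        chain = RewardChain(U=np.array([[0.8]]), rewards=np.array([0.4]),
                            labels=["h_0.5"])
        mom = wp.lrs_moments(chain)
        mean, var, skew = geometric_closed_forms(0.8, 0.4)
        assert mom["mean"].iloc[0] == pytest.approx(2.0, abs=1e-12)
        assert mom["mean"].iloc[0] == pytest.approx(mean, abs=1e-12)
        assert mom["var"].iloc[0] == pytest.approx(var, abs=1e-10)
        assert mom["skew"].iloc[0] == pytest.approx(skew, abs=1e-10)

    def test_zero_rewards_zero_moments(self):
        chain = RewardChain(U=np.array([[0.5, 0.0], [0.3, 0.6]]),
                            rewards=np.zeros(2), labels=["a", "b"])
        mom = wp.lrs_moments(chain)
        assert np.all(mom.to_numpy() == 0.0)

    def test_immortal_chain_rejected(self):
        chain = RewardChain(U=np.array([[1.0]]), rewards=np.array([0.2]),
                            labels=["a"])
        with pytest.raises(ValueError, match="immortal"):
            wp.lrs_moments(chain)

    def test_multi_state_moments_match_monte_carlo(self):
        """10^5 simulated lifetimes on a 3-state chain reproduce the
        analytic mean and variance within 3 standard errors."""
        U = np.array([[0.3, 0.0, 0.0],
                      [0.5, 0.6, 0.1],
                      [0.0, 0.2, 0.7]])
        p = np.array([0.1, 0.4, 0.25])
        chain = RewardChain(U=U, rewards=p, labels=["a", "b", "c"])
        mom = wp.lrs_moments(chain)

        rng = np.random.default_rng(123)
        n = 100_000
        cum = U.cumsum(axis=0)              # column i: transition cdf
        lrs = np.zeros(n)
        for k in range(n):
            state, total = 0, 0
            while state >= 0:
                total += rng.random() < p[state]
                r = rng.random()
                nxt = np.searchsorted(cum[:, state], r)
                state = nxt if nxt < 3 and r < cum[-1, state] else -1
            lrs[k] = total
        se_mean = lrs.std(ddof=1) / np.sqrt(n)
        assert mom["mean"].iloc[0] == pytest.approx(lrs.mean(), abs=3 * se_mean)
        m2 = (lrs - lrs.mean()) ** 2
        se_var = m2.std(ddof=1) / np.sqrt(n)
        assert mom["var"].iloc[0] == pytest.approx(lrs.var(ddof=1), abs=3 * se_var)


class TestCohorts:
    def test_zero_reproduction_gives_zero_lrs(self, default_kernel):
        import copy
        k = copy.deepcopy(default_kernel)
        k.intercepts["R_d"] = -800.0
        k.intercepts["R_h"] = -800.0
        cfg = wp.ModelConfig(horizon=60, burn_in=30)
        res = wp.track_cohort(k, cfg, "helper", n_cohorts=3, rng=0, max_steps=300)
        assert np.all(res.lrs == 0.0)

    def test_frozen_environment_equals_markov_reward_mean(self, default_kernel):
        """Method equivalence: in a time-homogeneous environment the cohort
        simulation and the reward-chain recursion agree."""
        cfg = wp.ModelConfig(horizon=60, burn_in=50)
        env = frozen_environment(default_kernel, cfg)
        chain = wp.build_reward_chain(default_kernel, cfg, env)
        mom = wp.lrs_moments(chain)
        for stage, label in (("helper", "h"), ("non-helper", "u")):
            res = wp.track_cohort(default_kernel, cfg, stage, n_cohorts=1, rng=0,
                                  frozen_intercepts=env.intercepts)
            markov = mom["mean"].iloc[chain.index_of(label, 0.5)]
            assert res.mean == pytest.approx(markov, abs=5e-4)

    def test_environmental_lrs_contains_no_zeros(self, default_kernel):
        cfg = wp.ModelConfig(horizon=250, burn_in=150)
        res = wp.track_cohort(default_kernel, cfg, "non-helper", n_cohorts=8, rng=4)
        assert np.all(res.lrs > 0.0)
        lo, hi = res.iqr
        assert lo <= res.median <= hi

    def test_trajectory_invariants(self, default_kernel):
        cfg = wp.ModelConfig(horizon=120, burn_in=80)
        res = wp.track_cohort(default_kernel, cfg, "helper", n_cohorts=2, rng=9,
                              record=True)
        for traj in res.trajectories:
            l = traj.survivorship
            assert l[0] == pytest.approx(1.0)
            assert np.all(np.diff(l) <= 1e-12)                 # non-increasing
            np.testing.assert_allclose(traj.occupancy.sum(axis=1), l, atol=1e-12)
            assert np.all(np.diff(traj.offspring_accrued) >= 0)

    def test_invalid_stage_rejected(self, default_kernel, short_config):
        with pytest.raises(ValueError, match="start_stage"):
            wp.track_cohort(default_kernel, short_config, "dominant", n_cohorts=1)


class TestReproductiveValues:
    def test_deterministic_limit_equals_classical_left_eigenvector(self, default_kernel):
        """With a single-season kernel the realized matrices are all equal at
        the fixed point, so the result is the classical left eigenvector."""
        kernel = constant_kernel(default_kernel.mean_intercepts().to_dict())
        cfg = wp.ModelConfig(horizon=900, burn_in=850)
        res = wp.simulate(kernel, cfg, rng=0)
        rv = wp.reproductive_values(kernel, cfg, res, n_matrices=10, n_boot=5, rng=1)

        env = frozen_environment(kernel, cfg)
        K = wp.build_projection_matrix(env.state, kernel, env.intercepts, cfg)
        _, v = _left_eigvec(K)
        np.testing.assert_allclose(rv.table["v"].to_numpy(), v / v[0], atol=1e-6)
        assert rv.table["v"].iloc[0] == 1.0

    def test_eigenvector_matches_marked_lineage_projection(self, default_kernel):
        """Forward-projecting a marked class and counting total descendants
        reproduces the reproductive-value ratios (power-method oracle)."""
        kernel = constant_kernel(default_kernel.mean_intercepts().to_dict())
        cfg = wp.ModelConfig(horizon=60, burn_in=50)
        env = frozen_environment(kernel, cfg)
        K = wp.build_projection_matrix(env.state, kernel, env.intercepts, cfg)
        _, v = _left_eigvec(K)
        T = 400
        KT = np.linalg.matrix_power(K, T)
        descendants = KT.sum(axis=0)          # total mass from one unit of class i
        np.testing.assert_allclose(descendants / descendants[0], v / v[0],
                                   rtol=1e-8)

    def test_nonhelper_value_declines_faster(self, default_kernel):
        """Non-helpers are promoted sooner, so their value is front-loaded:
        higher than helpers' at the youngest ages, lower later."""
        cfg = wp.ModelConfig(horizon=900, burn_in=500)
        res = wp.simulate(default_kernel, cfg, rng=13)
        rv = wp.reproductive_values(default_kernel, cfg, res,
                                    n_matrices=120, n_boot=10, rng=2)
        vh = rv.by_stage("h")["v"].to_numpy()
        vu = rv.by_stage("u")["v"].to_numpy()
        assert vu[0] > vh[0]
        assert np.all(vh[10:24] > vu[10:24])
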