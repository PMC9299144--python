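"""Fitness descriptors: cohort LRS, Markov-reward moments, reproductive values.

Three complementary descriptors of lifetime reproductive success (LRS)
and (st)age value:

* :func:`track_cohort` follows cohorts of newly recruited helpers or
  non-helpers through a stochastic resident population, accumulating
  expected offspring per original member until the cohort is extinct.
  Across-cohort variation reflects environmental stochasticity only, so
  cohort LRS is unimodal around its mean and contains no zeros.
* :func:`lrs_moments` computes the mean, variance, CV and skewness of
  LRS on an absorbing Markov chain with per-step Bernoulli rewards
  (individual demographic stochasticity); in a frozen environment its
  mean equals the cohort-simulation mean.
* :func:`reproductive_values` returns the (st)age-specific reproductive
  value as the dominant left eigenvector of the mean realized projection
  matrix at stochastic quasi-equilibrium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig
from .lottery import LotteryState, transition_probs, vacancy_count
from .projection import (
    PopulationState,
    SimulationResult,
    build_projection_matrix,
    class_labels,
    default_initial_state,
    draw_season,
    project_step,
)
from .rates import RateProfile, SeasonalParameterKernel, rate_profile

logger = logging.getLogger(__name__)

__all__ = [
    "RewardChain",
    "CohortResult",
    "CohortTrajectory",
    "frozen_environment",
    "build_reward_chain",
    "lrs_moments",
    "track_cohort",
    "reproductive_values",
]


# ---------------------------------------------------------------------
# Markov chains with rewards
# ---------------------------------------------------------------------

@dataclass
class RewardChain:
    """Absorbing chain over transient (st)age classes with Bernoulli rewards.

    ``U[j, i]`` is the probability that an individual in class ``i``
    survives into class ``j`` next step (column sums <= 1; the deficit
    is mortality). ``rewards[i]`` is the probability of producing one
    offspring while occupying class ``i`` for a step — because the
    per-step reward is Bernoulli, all its raw moments equal this
    probability. ``labels`` names the classes.
    """

    U: np.ndarray
    rewards: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.rewards = np.asarray(self.rewards, dtype=float)
        if self.U.shape[0] != self.U.shape[1] or self.U.shape[0] != self.rewards.size:
            raise ValueError("U must be square and match the reward vector")
        if np.any(self.U < 0) or np.any(self.U.sum(axis=0) > 1 + 1e-9):
            raise ValueError("U must be non-negative with column sums <= 1")
        if np.any((self.rewards < 0) | (self.rewards > 1)):
            raise ValueError("reward probabilities must lie in [0, 1]")

    def index_of(self, stage: str, age: float) -> int:
        return self.labels.index(f"{stage}_{age:g}")


def lrs_moments(chain: RewardChain) -> pd.DataFrame:
    """First three moments of accumulated Bernoulli rewards per starting class.

    Implements the moment recursions for an absorbing chain in which an
    individual occupying class ``i`` at a census collects an independent
    Bernoulli(``rewards[i]``) offspring, then survives into class ``j``
    with probability ``U[j, i]``. With ``rho_k`` the k-th raw moment of
    the remaining accumulated reward,

        rho1 = (I - U')^-1 p,
        rho2 = (I - U')^-1 (p + 2 p * (U' rho1)),
        rho3 = (I - U')^-1 (p + 3 p * (U' rho1) + 3 p * (U' rho2)),

    where ``p`` is the reward vector and ``*`` the elementwise product.
    Returns a frame indexed by class label with columns mean, var, cv,
    skew.

    Raises
    ------
    ValueError
        If the spectral radius of ``U`` is >= 1 (an immortal chain never
        absorbs, so LRS is undefined).
    """
    U = chain.U
    p = chain.rewards
    rho_spectral = np.max(np.abs(np.linalg.eigvals(U)))
    if rho_spectral >= 1.0 - 1e-12:
        raise ValueError(f"spectral radius of U is {rho_spectral:.6f} >= 1: immortal chain")
    n = U.shape[0]
    A = np.eye(n) - U.T
    rho1 = np.linalg.solve(A, p)
    rho2 = np.linalg.solve(A, p + 2 * p * (U.T @ rho1))
    rho3 = np.linalg.solve(A, p + 3 * p * (U.T @ rho1) + 3 * p * (U.T @ rho2))
    var = rho2 - rho1**2
    var = np.where(np.abs(var) < 1e-15, 0.0, var)
    m3 = rho3 - 3 * rho1 * rho2 + 2 * rho1**3
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(rho1 > 0, np.sqrt(np.maximum(var, 0)) / rho1, 0.0)
        skew = np.where(var > 0, m3 / np.maximum(var, 1e-300) ** 1.5, 0.0)
    return pd.DataFrame(
        {"mean": rho1, "var": var, "cv": cv, "skew": skew}, index=chain.labels
    )


# ---------------------------------------------------------------------
# frozen environment helpers
# ---------------------------------------------------------------------

@dataclass
class FrozenEnvironment:
    """A deterministic fixed point of the projection under fixed intercepts."""

    state: PopulationState
    intercepts: pd.Series
    profile: RateProfile
    x: float
    g_h: float
    g_u: float


def frozen_environment(kernel: SeasonalParameterKernel, config: ModelConfig,
                       intercepts=None, max_iter: int = 5000,
                       tol: float = 1e-12) -> FrozenEnvironment:
    """Iterate the deterministic projection (fixed intercepts) to its fixed point."""
    if intercepts is None:
        intercepts = kernel.mean_intercepts()
    state = default_initial_state(config)
    prev = None
    for _ in range(max_iter):
        state, _info = project_step(state, kernel, intercepts, config)
        vec = np.concatenate([state.d, state.h, state.u])
        if prev is not None and np.max(np.abs(vec - prev)) < tol:
            break
        prev = vec
    else:
        logger.warning("frozen environment did not reach tolerance %g", tol)
    prof = rate_profile(kernel, intercepts, config,
                        pop_size_raw=state.total, ratio=state.ratio)
    x = vacancy_count(config.termax, prof.S_d * state.d)
    g_h, g_u = transition_probs(LotteryState(
        x, float(np.sum(prof.S_h * state.h)), float(np.sum(prof.S_u * state.u)),
        config.beta))
    return FrozenEnvironment(state=state, intercepts=intercepts, profile=prof,
                             x=x, g_h=g_h, g_u=g_u)


def build_reward_chain(kernel: SeasonalParameterKernel, config: ModelConfig,
                       env: FrozenEnvironment | None = None) -> RewardChain:
    """Reward chain for one individual in a frozen environment.

    The transient matrix is the realized projection matrix with the
    reproduction rows removed (newborns are rewards, not transitions of
    the focal individual); rewards are the per-class reproduction
    probabilities — the helper-presence mixture for dominants, ``R_h``
    for helpers, zero for non-helpers.
    """
    if env is None:
        env = frozen_environment(kernel, config)
    cfg = kernel.apply_standardisation(config)
    K = build_projection_matrix(env.state, kernel, env.intercepts, cfg)
    n_dom, n_sub = cfg.n_dom, cfg.n_sub
    i_h0 = n_dom
    i_u0 = n_dom + n_sub
    U = K.copy()
    U[i_h0, :] = 0.0      # the only inflows to the first subordinate
    U[i_u0, :] = 0.0      # classes are births
    prof = env.profile
    R_dom = prof.p_help * prof.R_d_q1 + (1 - prof.p_help) * prof.R_d_q0
    rewards = np.concatenate([R_dom, prof.R_h, np.zeros(n_sub)])
    return RewardChain(U=U, rewards=rewards, labels=class_labels(cfg))


# ---------------------------------------------------------------------
# cohort tracking
# ---------------------------------------------------------------------

@dataclass
class CohortTrajectory:
    """Survivorship and offspring accumulation of one cohort."""

    survivorship: np.ndarray          # l(t), starting at 1.0
    occupancy: np.ndarray             # (T, 3): mass in d, h, u
    offspring_accrued: np.ndarray     # cumulative expected offspring per member


@dataclass
class CohortResult:
    """Distribution of cohort LRS under environmental stochasticity."""

    start_stage: str
    lrs: np.ndarray
    trajectories: list[CohortTrajectory] | None = None

    @property
    def median(self) -> float:
        return float(np.median(self.lrs))

    @property
    def iqr(self) -> tuple[float, float]:
        return (float(np.quantile(self.lrs, 0.25)), float(np.quantile(self.lrs, 0.75)))

    @property
    def mean(self) -> float:
        return float(np.mean(self.lrs))


def _cohort_step(cd, ch, cu, prof: RateProfile, g_h: float, g_u: float,
                 config: ModelConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Advance a cohort's per-capita occupancy one step; return new masses and reward."""
    n_dom, n_sub = config.n_dom, config.n_sub
    R_dom = prof.p_help * prof.R_d_q1 + (1 - prof.p_help) * prof.R_d_q0
    reward = float(np.sum(R_dom * cd) + np.sum(prof.R_h * ch))

    sd = prof.S_d * cd
    sh = prof.S_h * ch
    su = prof.S_u * cu
    new_d = np.zeros(n_dom)
    new_d[1:] += sd[:-1]
    new_d[-1] += sd[-1]
    idx = np.minimum(np.arange(n_sub), n_dom - 1)
    np.add.at(new_d, idx, g_h * sh + g_u * su)
    new_h = np.zeros(n_sub)
    new_u = np.zeros(n_sub)
    new_h[1:] += (1 - g_h) * sh[:-1]
    new_h[-1] += (1 - g_h) * sh[-1]
    new_u[1:] += (1 - g_u) * su[:-1]
    new_u[-1] += (1 - g_u) * su[-1]
    return new_d, new_h, new_u, reward


def track_cohort(kernel: SeasonalParameterKernel, config: ModelConfig,
                 start_stage: str, n_cohorts: int = 100,
                 rng: np.random.Generator | int | None = None,
                 extinction_tol: float = 1e-10, max_steps: int = 2000,
                 record: bool = False,
                 frozen_intercepts=None) -> CohortResult:
    """Follow cohorts of new recruits through stochastic resident populations.

    Each replicate spins up its own resident population (``config.burn_in``
    steps), then starts a cohort as unit mass at the first subordinate
    age class of ``start_stage`` ('helper' or 'non-helper'). The cohort
    experiences the resident environment's per-step rates — including
    lottery promotion to dominance and subsequent dominant reproduction —
    and accumulates expected offspring per original member until its
    survivorship falls below ``extinction_tol``. Within a replicate the
    cohort and the resident population share the same seasonal draws;
    draws are fresh across replicates.

    Pass ``frozen_intercepts`` to run every replicate in the same
    deterministic environment (used for the Markov-reward equivalence).
    """
    if start_stage not in ("helper", "non-helper"):
        raise ValueError("start_stage must be 'helper' or 'non-helper'")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cfg = kernel.apply_standardisation(config)
    n_dom, n_sub = cfg.n_dom, cfg.n_sub
    lrs = np.empty(n_cohorts)
    trajectories: list[CohortTrajectory] | None = [] if record else None

    for rep in range(n_cohorts):
        state = default_initial_state(cfg)
        for _ in range(cfg.burn_in):
            if frozen_intercepts is None:
                _, intercepts = draw_season(kernel, rng)
            else:
                intercepts = frozen_intercepts
            state, _ = project_step(state, kernel, intercepts, cfg)

        cd = np.zeros(n_dom)
        ch = np.zeros(n_sub)
        cu = np.zeros(n_sub)
        if start_stage == "helper":
            ch[0] = 1.0
        else:
            cu[0] = 1.0
        total_reward = 0.0
        l_series, occ_series, acc_series = [], [], []
        steps = 0
        while cd.sum() + ch.sum() + cu.sum() > extinction_tol:
            if steps >= max_steps:
                logger.warning(
                    "cohort not extinct after %d steps (mass %.3g); truncating",
                    max_steps, cd.sum() + ch.sum() + cu.sum())
                break
            if frozen_intercepts is None:
                _, intercepts = draw_season(kernel, rng)
            else:
                intercepts = frozen_intercepts
            prof = rate_profile(kernel, intercepts, cfg,
                                pop_size_raw=state.total, ratio=state.ratio)
            sdom = prof.S_d * state.d
            x = vacancy_count(cfg.termax, sdom)
            g_h, g_u = transition_probs(LotteryState(
                x, float(np.sum(prof.S_h * state.h)),
                float(np.sum(prof.S_u * state.u)), cfg.beta))
            if record:
                l_series.append(cd.sum() + ch.sum() + cu.sum())
                occ_series.append((cd.sum(), ch.sum(), cu.sum()))
                acc_series.append(total_reward)
            cd, ch, cu, reward = _cohort_step(cd, ch, cu, prof, g_h, g_u, cfg)
            total_reward += reward
            # advance the resident population with the same season draw
            from .projection import _advance
            state, _ = _advance(state, prof, cfg, cfg.beta)
            steps += 1
        lrs[rep] = total_reward
        if record:
            trajectories.append(CohortTrajectory(
                survivorship=np.asarray(l_series),
                occupancy=np.asarray(occ_series),
                offspring_accrued=np.asarray(acc_series)))
    return CohortResult(start_stage=start_stage, lrs=lrs, trajectories=trajectories)


# ---------------------------------------------------------------------
# reproductive values
# ---------------------------------------------------------------------

@dataclass
class RVResult:
    """Reproductive values by (st)age with interquartile bands."""

    table: pd.DataFrame       # columns: stage, age, v, lo, hi
    eigenvalue: float

    def by_stage(self, stage: str) -> pd.DataFrame:
        return self.table[self.table["stage"] == stage].reset_index(drop=True)


def _left_eigvec(K: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eig(K.T)
    i = int(np.argmax(np.abs(vals)))
    lam = vals[i]
    v = vecs[:, i]
    if np.max(np.abs(v.imag)) > 1e-8 * np.max(np.abs(v.real)):
        raise ValueError("dominant left eigenvector is not real; power iteration failed")
    v = v.real
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-8 * np.max(np.abs(v))):
        raise ValueError("dominant left eigenvector has mixed signs")
    return float(lam.real), np.maximum(v, 0.0)


def reproductive_values(kernel: SeasonalParameterKernel, config: ModelConfig,
                        result: SimulationResult, n_matrices: int = 300,
                        n_boot: int = 50,
                        rng: np.random.Generator | int | None = None) -> RVResult:
    """(St)age-specific reproductive values at stochastic quasi-equilibrium.

    Rebuilds the realized per-capita projection matrix at a subsample of
    post-burn-in steps, averages them, and returns the dominant left
    eigenvector normalised so the youngest dominant class has value 1.
    Interquartile bands come from bootstrap resamples of the step-wise
    matrices.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cfg = kernel.apply_standardisation(config)
    post = result.post_burn_in
    if len(post) == 0 or result.states_d.shape[0] == 0:
        raise ValueError("need a post-burn-in ensemble; run simulate with store_states=True")
    # stored state k is the census at time burn_in + k; summary row t uses the
    # census at t, so row t pairs with stored index t - burn_in
    ts = post["t"].to_numpy()
    usable = ts[ts - result.config.burn_in < result.states_d.shape[0]]
    take = np.linspace(0, usable.size - 1, min(n_matrices, usable.size)).astype(int)
    mats = []
    from .rates import CHANNELS
    for t in usable[take]:
        k = int(t - result.config.burn_in)
        state = PopulationState(d=result.states_d[k], h=result.states_h[k],
                                u=result.states_u[k])
        row = post.loc[post["t"] == t].iloc[0]
        intercepts = pd.Series({ch: row[f"b0_{ch}"] for ch in CHANNELS})
        mats.append(build_projection_matrix(state, kernel, intercepts, cfg))
    mats = np.asarray(mats)

    lam, v = _left_eigvec(mats.mean(axis=0))
    v = v / v[0]                       # youngest dominant class has value 1
    boots = np.empty((n_boot, v.size))
    for b in range(n_boot):
        pick = rng.integers(0, mats.shape[0], size=mats.shape[0])
        _, vb = _left_eigvec(mats[pick].mean(axis=0))
        boots[b] = vb / vb[0]
    lo = np.quantile(boots, 0.25, axis=0)
    hi = np.quantile(boots, 0.75, axis=0)

    stages = (["d"] * cfg.n_dom) + (["h"] * cfg.n_sub) + (["u"] * cfg.n_sub)
    ages = np.concatenate([cfg.dom_ages, cfg.sub_ages, cfg.sub_ages])
    table = pd.DataFrame({"stage": stages, "age": ages, "v": v, "lo": lo, "hi": hi})
    return RVResult(table=table, eigenvalue=lam)
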