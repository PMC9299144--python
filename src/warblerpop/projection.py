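"""Nonlinear, stochastic, density-dependent (st)age-structured projection.

One census step moves the dominant (``d``), helper (``h``) and
non-helper (``u``) age-density vectors forward half a year:

* survival of every (st)age class at its logistic rate, with the
  standardised population size and subordinate ratio computed from the
  time-``t`` census;
* dominant vacancies ``x = max(0, termax - sum(S_d * d))`` filled by the
  weighted lottery, promoted subordinates entering the dominant vector
  aged ``a + 0.5``;
* remaining subordinate survivors ageing within their stage (helpers
  never become non-helpers or vice versa);
* reproduction from time-``t`` counts — helpers at ``R_h``, dominants at
  the helper-presence mixture ``p(a,r)*R_d(q=1) + (1-p(a,r))*R_d(q=0)``
  — with each newborn entering at age 0.5 as a helper with probability
  ``f(mother's age, N)``, else as a non-helper;
* a recursive top age class (survivors of the maximum age remain in it).

Densities are continuous expected values; environmental stochasticity
enters through joint resampling of one observed season's intercept
vector per step (no temporal autocorrelation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfig
from .lottery import LotteryState, transition_probs, vacancy_count
from .rates import CHANNELS, RateProfile, SeasonalParameterKernel, rate_profile

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationState",
    "StepInfo",
    "SimulationResult",
    "draw_season",
    "project_step",
    "simulate",
    "default_initial_state",
    "stage_age_distribution",
    "build_projection_matrix",
]


@dataclass
class PopulationState:
    """Densities by stage and half-year age class at one census.

    ``d`` spans the dominant grid (ages 1.0..15.0 by default, 29
    classes); ``h`` and ``u`` span the subordinate grid (0.5..15.0,
    30 classes). There is no 0.5-year dominant class: offspring enter
    only as helpers or non-helpers.
    """

    d: np.ndarray
    h: np.ndarray
    u: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        for name in ("d", "h", "u"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"stage vector {name!r} must be finite and non-negative")

    @property
    def total(self) -> float:
        return float(self.d.sum() + self.h.sum() + self.u.sum())

    @property
    def totals(self) -> tuple[float, float, float]:
        return float(self.d.sum()), float(self.h.sum()), float(self.u.sum())

    @property
    def ratio(self) -> float:
        """Subordinates over dominants (0 when no dominants are present)."""
        nd = self.d.sum()
        return float((self.h.sum() + self.u.sum()) / nd) if nd > 0 else 0.0

    def validate_grid(self, config: ModelConfig) -> None:
        if self.d.size != config.n_dom or self.h.size != config.n_sub or self.u.size != config.n_sub:
            raise ValueError(
                f"state dimensions ({self.d.size},{self.h.size},{self.u.size}) do not match "
                f"the configured grids ({config.n_dom},{config.n_sub},{config.n_sub})"
            )


@dataclass
class StepInfo:
    """Diagnostics for one projection step."""

    x: float
    g_h: float
    g_u: float
    births_h: float
    births_u: float
    cap_bound: bool


def default_initial_state(config: ModelConfig) -> PopulationState:
    """Uniform low-density start; the burn-in removes initialisation effects."""
    d = np.full(config.n_dom, 0.9 * config.termax / config.n_dom)
    h = np.full(config.n_sub, 40.0 / config.n_sub)
    u = np.full(config.n_sub, 15.0 / config.n_sub)
    return PopulationState(d=d, h=h, u=u, time=0.0)


def draw_season(kernel: SeasonalParameterKernel, rng: np.random.Generator):
    """Draw one observed season uniformly; all channels take its intercepts jointly.

    Joint resampling of the whole row preserves the within-season
    covariance between vital rates; draws are independent across steps.
    """
    idx = int(rng.integers(kernel.n_seasons))
    season = kernel.intercepts.index[idx]
    return season, kernel.intercepts.iloc[idx]


def _advance(state: PopulationState, prof: RateProfile, config: ModelConfig,
             beta: float) -> tuple[PopulationState, StepInfo]:
    """Apply one census step for a fixed rate profile."""
    n_dom, n_sub = config.n_dom, config.n_sub

    surviving_dominants = prof.S_d * state.d
    x = vacancy_count(config.termax, surviving_dominants)
    sh = prof.S_h * state.h
    su = prof.S_u * state.u
    g_h, g_u = transition_probs(
        LotteryState(vacancies_x=x, surviving_helpers_nh=float(sh.sum()),
                     surviving_nonhelpers_nu=float(su.sum()), beta=beta)
    )
    w = np.exp(beta)
    denom = w * sh.sum() + su.sum()
    cap_bound = bool(denom > 0 and (x / denom > 1.0 or w * x / denom > 1.0))

    # dominants: ageing survivors plus promoted subordinates (aged a + step)
    new_d = np.zeros(n_dom)
    new_d[1:] += surviving_dominants[:-1]
    new_d[-1] += surviving_dominants[-1]          # recursive top class
    promoted = g_h * sh + g_u * su                # indexed by subordinate age
    idx = np.minimum(np.arange(n_sub), n_dom - 1)
    np.add.at(new_d, idx, promoted)

    # subordinates ageing within stage
    stay_h = (1.0 - g_h) * sh
    stay_u = (1.0 - g_u) * su
    new_h = np.zeros(n_sub)
    new_u = np.zeros(n_sub)
    new_h[1:] += stay_h[:-1]
    new_h[-1] += stay_h[-1]
    new_u[1:] += stay_u[:-1]
    new_u[-1] += stay_u[-1]

    # reproduction from time-t counts; newborns enter at age `step`
    R_dom = prof.p_help * prof.R_d_q1 + (1.0 - prof.p_help) * prof.R_d_q0
    births_from_dom = R_dom * state.d
    births_from_help = prof.R_h * state.h
    births_h = float(np.sum(prof.f_dom * births_from_dom) + np.sum(prof.f_sub * births_from_help))
    births_u = float(np.sum((1 - prof.f_dom) * births_from_dom)
                     + np.sum((1 - prof.f_sub) * births_from_help))
    new_h[0] += births_h
    new_u[0] += births_u

    for name, v in (("d", new_d), ("h", new_h), ("u", new_u)):
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise FloatingPointError(f"non-finite density in stage {name!r}, class index {bad}")
        if np.any(v < 0):
            raise FloatingPointError(f"negative density produced in stage {name!r}")

    new_state = PopulationState(d=new_d, h=new_h, u=new_u, time=state.time + config.step)
    return new_state, StepInfo(x=x, g_h=g_h, g_u=g_u, births_h=births_h,
                               births_u=births_u, cap_bound=cap_bound)


def project_step(state: PopulationState, kernel: SeasonalParameterKernel,
                 intercepts, config: ModelConfig) -> tuple[PopulationState, StepInfo]:
    """One census step under the given per-season intercept vector.

    Covariates (standardised N, subordinate ratio) are computed from the
    time-``t`` census of ``state``. Returns the state at ``t + step``
    and step diagnostics.
    """
    state.validate_grid(config)
    prof = rate_profile(kernel, intercepts, config,
                        pop_size_raw=state.total, ratio=state.ratio)
    return _advance(state, prof, config, config.beta)


@dataclass
class SimulationResult:
    """Trajectory summary plus the post-burn-in state ensemble."""

    summary: pd.DataFrame
    states_d: np.ndarray          # (n_post, n_dom)
    states_h: np.ndarray          # (n_post, n_sub)
    states_u: np.ndarray          # (n_post, n_sub)
    config: ModelConfig
    final_state: PopulationState
    extinct_at: int | None = None

    @property
    def post_burn_in(self) -> pd.DataFrame:
        return self.summary[self.summary["t"] >= self.config.burn_in]

    @property
    def mean_population_size(self) -> float:
        """Stochastic mean population size N-hat over the stationary ensemble."""
        return float(self.post_burn_in["N"].mean())

    def stage_means(self) -> dict[str, float]:
        post = self.post_burn_in
        return {s: float(post[f"n_{s}"].mean()) for s in ("d", "h", "u")}

    def stage_sds(self) -> dict[str, float]:
        post = self.post_burn_in
        return {s: float(post[f"n_{s}"].std(ddof=1)) for s in ("d", "h", "u")}


def simulate(kernel: SeasonalParameterKernel, config: ModelConfig,
             initial_state: PopulationState | None = None,
             rng: np.random.Generator | int | None = None,
             store_states: bool = True) -> SimulationResult:
    """Run the stochastic projection for ``config.horizon`` steps.

    Reproducible given a seed (``rng`` may be a Generator, an int seed,
    or None to fall back on ``config.seed``). If the population drops
    below ``config.extinction_tol`` the run is truncated and the
    extinction time logged.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    config = kernel.apply_standardisation(config)
    state = default_initial_state(config) if initial_state is None else initial_state
    state.validate_grid(config)

    rows = []
    kept_d, kept_h, kept_u = [], [], []
    extinct_at = None
    for t in range(config.horizon):
        season, intercepts = draw_season(kernel, rng)
        nd, nh, nu = state.totals
        row = {
            "t": t, "season": season, "N": state.total,
            "n_d": nd, "n_h": nh, "n_u": nu, "ratio": state.ratio,
        }
        state, info = project_step(state, kernel, intercepts, config)
        row.update({"x": info.x, "g_h": info.g_h, "g_u": info.g_u,
                    "cap_bound": info.cap_bound})
        for ch in CHANNELS:
            row[f"b0_{ch}"] = float(intercepts[ch])
        rows.append(row)
        if t + 1 >= config.burn_in and store_states:
            kept_d.append(state.d.copy())
            kept_h.append(state.h.copy())
            kept_u.append(state.u.copy())
        if state.total < config.extinction_tol:
            extinct_at = t + 1
            logger.warning("population extinct at step %d; truncating simulation", extinct_at)
            break

    summary = pd.DataFrame(rows)
    return SimulationResult(
        summary=summary,
        states_d=np.asarray(kept_d) if kept_d else np.empty((0, config.n_dom)),
        states_h=np.asarray(kept_h) if kept_h else np.empty((0, config.n_sub)),
        states_u=np.asarray(kept_u) if kept_u else np.empty((0, config.n_sub)),
        config=config,
        final_state=state,
        extinct_at=extinct_at,
    )


# ---------------------------------------------------------------------
# stationary (st)age distributions
# ---------------------------------------------------------------------

def stage_age_distribution(result: SimulationResult,
                           quantiles: tuple[float, float] = (0.25, 0.75)) -> dict[str, pd.DataFrame]:
    """Normalised stationary age distribution per stage with quantile bands.

    For each stage the per-step age vector is normalised to sum to one
    and the mean and across-step quantiles are tabulated. Returns a
    mapping stage -> DataFrame(age, mean, lo, hi); the mean column of
    each frame sums to 1.
    """
    cfg = result.config
    out: dict[str, pd.DataFrame] = {}
    grids = {"d": cfg.dom_ages, "h": cfg.sub_ages, "u": cfg.sub_ages}
    stacks = {"d": result.states_d, "h": result.states_h, "u": result.states_u}
    for stage, ages in grids.items():
        arr = stacks[stage]
        if arr.shape[0] == 0:
            raise ValueError("empty state ensemble; run simulate with store_states=True")
        totals = arr.sum(axis=1, keepdims=True)
        norm = np.divide(arr, totals, out=np.zeros_like(arr), where=totals > 0)
        mean = norm.mean(axis=0)
        s = mean.sum()
        if s > 0:
            mean = mean / s
        lo = np.quantile(norm, quantiles[0], axis=0)
        hi = np.quantile(norm, quantiles[1], axis=0)
        out[stage] = pd.DataFrame({"age": ages, "mean": mean, "lo": lo, "hi": hi})
    return out


def mass_below_age(dist: pd.DataFrame, age: float) -> float:
    """Fraction of a stage's stationary distribution younger than ``age``."""
    return float(dist.loc[dist["age"] < age, "mean"].sum())


# ---------------------------------------------------------------------
# realized per-capita projection matrix
# ---------------------------------------------------------------------

def class_labels(config: ModelConfig) -> list[str]:
    """Labels of the stacked class vector: dominants, helpers, non-helpers."""
    return (
        [f"d_{a:g}" for a in config.dom_ages]
        + [f"h_{a:g}" for a in config.sub_ages]
        + [f"u_{a:g}" for a in config.sub_ages]
    )


def build_projection_matrix(state: PopulationState, kernel: SeasonalParameterKernel,
                            intercepts, config: ModelConfig) -> np.ndarray:
    """Realized projection matrix ``K`` frozen at this state and season.

    ``K`` reproduces :func:`project_step` exactly for the given state:
    ``K @ stack(state) == stack(project_step(state, ...))``, with the
    nonlinear quantities (standardised N, ratio, vacancies, lottery
    probabilities) evaluated at ``state`` and held fixed. Classes are
    stacked dominants (ages 1..m), then helpers, then non-helpers.
    """
    state.validate_grid(config)
    cfg = kernel.apply_standardisation(config)
    prof = rate_profile(kernel, intercepts, cfg,
                        pop_size_raw=state.total, ratio=state.ratio)
    n_dom, n_sub = cfg.n_dom, cfg.n_sub
    n = n_dom + 2 * n_sub
    K = np.zeros((n, n))
    i_d = np.arange(n_dom)
    i_h = n_dom + np.arange(n_sub)
    i_u = n_dom + n_sub + np.arange(n_sub)

    sh_tot = float(np.sum(prof.S_h * state.h))
    su_tot = float(np.sum(prof.S_u * state.u))
    x = vacancy_count(cfg.termax, prof.S_d * state.d)
    g_h, g_u = transition_probs(LotteryState(x, sh_tot, su_tot, cfg.beta))

    # dominant survival/ageing
    for j in range(n_dom):
        dest = min(j + 1, n_dom - 1)
        K[i_d[dest], i_d[j]] += prof.S_d[j]
    # subordinate survival: promotion vs staying
    sub_dest_dom = np.minimum(np.arange(n_sub), n_dom - 1)
    for j in range(n_sub):
        K[i_d[sub_dest_dom[j]], i_h[j]] += g_h * prof.S_h[j]
        K[i_d[sub_dest_dom[j]], i_u[j]] += g_u * prof.S_u[j]
        dest = min(j + 1, n_sub - 1)
        K[i_h[dest], i_h[j]] += (1 - g_h) * prof.S_h[j]
        K[i_u[dest], i_u[j]] += (1 - g_u) * prof.S_u[j]
    # reproduction rows (newborns enter the first subordinate class)
    R_dom = prof.p_help * prof.R_d_q1 + (1 - prof.p_help) * prof.R_d_q0
    K[i_h[0], i_d] += prof.f_dom * R_dom
    K[i_u[0], i_d] += (1 - prof.f_dom) * R_dom
    K[i_h[0], i_h] += prof.f_sub * prof.R_h
    K[i_u[0], i_h] += (1 - prof.f_sub) * prof.R_h
    return K


def stack_state(state: PopulationState) -> np.ndarray:
    """Stack a state into the (d, h, u) class vector used by ``K``."""
    return np.concatenate([state.d, state.h, state.u])
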