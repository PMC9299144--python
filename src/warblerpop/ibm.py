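"""Individual-based model (IBM) mirroring the expected-value projection.

The IBM realises the same life cycle at the level of discrete birds:
Bernoulli survival per individual at its (st)age rate, integer
vacancies (capacity rounded to a whole number of territories, since
discrete birds cannot hold a fifth of one), sequential weighted
sampling without replacement for territory acquisition (helpers with
weight ``exp(beta)``, non-helpers with weight 1), Bernoulli
reproduction with drawn helper-presence status, and stochastic
recruitment of each newborn as a helper or non-helper. Averaged over
replicates its per-step expected change matches the matrix projection;
single runs add demographic stochasticity, which is what makes
individual-level lifetime reproductive success zero-inflated while
cohort-level LRS is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfig
from .projection import PopulationState, default_initial_state, draw_season
from .rates import SeasonalParameterKernel, rate_profile

__all__ = [
    "IBMState",
    "ibm_step",
    "run_ibm",
    "ibm_state_from_densities",
    "posterior_predictive_check",
    "PPCResult",
]

STAGE_D, STAGE_H, STAGE_U = 0, 1, 2
_STAGE_LABEL = {STAGE_D: "d", STAGE_H: "h", STAGE_U: "u"}


@dataclass
class IBMState:
    """Discrete birds: parallel arrays of id, age and stage."""

    ids: np.ndarray
    ages: np.ndarray
    stages: np.ndarray
    next_id: int = 0
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.next_id == 0 and self.ids.size:
            self.next_id = int(self.ids.max()) + 1

    @property
    def n(self) -> int:
        return self.ids.size

    def counts(self) -> tuple[int, int, int]:
        return (int(np.sum(self.stages == STAGE_D)),
                int(np.sum(self.stages == STAGE_H)),
                int(np.sum(self.stages == STAGE_U)))

    def to_population_state(self, config: ModelConfig) -> PopulationState:
        """Tabulate individuals into the density representation."""
        d = np.zeros(config.n_dom)
        h = np.zeros(config.n_sub)
        u = np.zeros(config.n_sub)
        for stage, vec, offset in ((STAGE_D, d, 2), (STAGE_H, h, 1), (STAGE_U, u, 1)):
            sel = self.stages == stage
            idx = np.round(self.ages[sel] / config.step).astype(int) - offset
            np.add.at(vec, np.clip(idx, 0, vec.size - 1), 1.0)
        return PopulationState(d=d, h=h, u=u, time=self.time)


def ibm_state_from_densities(state: PopulationState, config: ModelConfig) -> IBMState:
    """Build an integer population by rounding each class density."""
    ids, ages, stages = [], [], []
    nid = 0
    for stage, vec, grid in ((STAGE_D, state.d, config.dom_ages),
                             (STAGE_H, state.h, config.sub_ages),
                             (STAGE_U, state.u, config.sub_ages)):
        for a, dens in zip(grid, vec):
            k = int(round(dens))
            for _ in range(k):
                ids.append(nid)
                ages.append(a)
                stages.append(stage)
                nid += 1
    return IBMState(ids=np.array(ids, dtype=np.int64),
                    ages=np.array(ages, dtype=float),
                    stages=np.array(stages, dtype=np.int8),
                    next_id=nid, time=state.time)


def _weighted_sample_without_replacement(weights: np.ndarray, k: int,
                                         rng: np.random.Generator) -> np.ndarray:
    """Indices of ``k`` sequential weighted draws without replacement.

    Exponential-race formulation of successive sampling: each item draws
    an Exp(weight) arrival time and the first ``k`` arrivals win — ties
    broken by the draws themselves.
    """
    times = rng.exponential(1.0, size=weights.size) / weights
    return np.argsort(times)[:k]


def ibm_step(ibm: IBMState, kernel: SeasonalParameterKernel, intercepts,
             config: ModelConfig, rng: np.random.Generator
             ) -> tuple[IBMState, pd.DataFrame]:
    """One half-year season of the individual-based model.

    Returns the next-season population and an event table with one row
    per bird present at the census (id, age, stage, alive, reproduced,
    promoted) plus one row per newborn (carrying ``mother_id``).
    Reproduction uses the time-``t`` census, as in the matrix model, so
    a bird may leave an offspring in the season it dies.
    """
    cfg = kernel.apply_standardisation(config)
    n_dom = cfg.n_dom
    nd, nh, nu = ibm.counts()
    N_raw = float(ibm.n)
    ratio = (nh + nu) / nd if nd > 0 else 0.0
    prof = rate_profile(kernel, intercepts, cfg, pop_size_raw=N_raw, ratio=ratio)

    sub_idx = np.round(ibm.ages / cfg.step).astype(int) - 1          # subordinate grids
    dom_idx = np.clip(np.round(ibm.ages / cfg.step).astype(int) - 2, 0, n_dom - 1)
    surv_p = np.empty(ibm.n)
    is_d = ibm.stages == STAGE_D
    is_h = ibm.stages == STAGE_H
    is_u = ibm.stages == STAGE_U
    surv_p[is_d] = prof.S_d[dom_idx[is_d]]
    surv_p[is_h] = prof.S_h[sub_idx[is_h]]
    surv_p[is_u] = prof.S_u[sub_idx[is_u]]
    alive = rng.random(ibm.n) < surv_p

    # integer vacancies: whole territories minus surviving dominants
    termax_int = int(round(cfg.termax))
    x = max(0, termax_int - int(np.sum(alive & is_d)))
    pool = np.flatnonzero(alive & ~is_d)
    promoted = np.zeros(ibm.n, dtype=bool)
    if x > 0 and pool.size > 0:
        weights = np.where(ibm.stages[pool] == STAGE_H, np.exp(cfg.beta), 1.0)
        winners = pool[_weighted_sample_without_replacement(weights, min(x, pool.size), rng)]
        promoted[winners] = True

    # reproduction from the time-t census (independent of the survival draw)
    reproduced = np.zeros(ibm.n, dtype=bool)
    helped = np.zeros(ibm.n, dtype=bool)
    if np.any(is_d):
        p_h = prof.p_help[dom_idx[is_d]]
        q = rng.random(p_h.size) < p_h
        helped[is_d] = q
        r_p = np.where(q, prof.R_d_q1[dom_idx[is_d]], prof.R_d_q0[dom_idx[is_d]])
        reproduced[is_d] = rng.random(r_p.size) < r_p
    if np.any(is_h):
        reproduced[is_h] = rng.random(int(is_h.sum())) < prof.R_h[sub_idx[is_h]]

    mothers = np.flatnonzero(reproduced)
    f_p = np.empty(mothers.size)
    md = is_d[mothers]
    f_p[md] = prof.f_dom[dom_idx[mothers[md]]]
    f_p[~md] = prof.f_sub[sub_idx[mothers[~md]]]
    newborn_helper = rng.random(mothers.size) < f_p

    events = pd.DataFrame({
        "id": ibm.ids,
        "age": ibm.ages,
        "stage": np.vectorize(_STAGE_LABEL.get)(ibm.stages) if ibm.n else np.array([], dtype=object),
        "alive": alive.astype(int),
        "reproduced": reproduced.astype(int),
        "promoted": promoted.astype(int),
        "helped": helped.astype(int),
        "mother_id": np.full(ibm.n, -1, dtype=np.int64),
    })

    # assemble next season: survivors age (recursive top class), promoted change stage
    keep = alive
    new_ages = np.minimum(ibm.ages[keep] + cfg.step, cfg.age_max)
    new_stages = ibm.stages[keep].copy()
    new_stages[promoted[keep]] = STAGE_D
    new_ids = ibm.ids[keep]

    n_born = mothers.size
    born_ids = ibm.next_id + np.arange(n_born, dtype=np.int64)
    born_stages = np.where(newborn_helper, STAGE_H, STAGE_U).astype(np.int8)
    born_rows = pd.DataFrame({
        "id": born_ids,
        "age": np.full(n_born, cfg.step),
        "stage": np.vectorize(_STAGE_LABEL.get)(born_stages) if n_born else np.array([], dtype=object),
        "alive": np.ones(n_born, dtype=int),
        "reproduced": np.zeros(n_born, dtype=int),
        "promoted": np.zeros(n_born, dtype=int),
        "helped": np.zeros(n_born, dtype=int),
        "mother_id": ibm.ids[mothers],
    })
    events = pd.concat([events, born_rows], ignore_index=True) if n_born else events

    nxt = IBMState(
        ids=np.concatenate([new_ids, born_ids]),
        ages=np.concatenate([new_ages, np.full(n_born, cfg.step)]),
        stages=np.concatenate([new_stages, born_stages]),
        next_id=int(ibm.next_id + n_born),
        time=ibm.time + cfg.step,
    )
    return nxt, events


@dataclass
class IBMRun:
    """Outcome of a multi-season IBM simulation."""

    counts: pd.DataFrame          # one row per season: N, n_d, n_h, n_u, ratio
    records: pd.DataFrame         # per-bird-season event rows
    lrs: pd.DataFrame             # per-individual offspring totals (dead birds only)


def run_ibm(kernel: SeasonalParameterKernel, config: ModelConfig, n_steps: int,
            initial: IBMState | None = None,
            rng: np.random.Generator | int | None = None,
            collect_records: bool = True) -> IBMRun:
    """Run the IBM for ``n_steps`` seasons with kernel-resampled intercepts."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cfg = kernel.apply_standardisation(config)
    ibm = ibm_state_from_densities(default_initial_state(cfg), cfg) if initial is None else initial

    offspring: dict[int, int] = {}
    died: set[int] = set()
    all_events = []
    count_rows = []
    for t in range(n_steps):
        _, intercepts = draw_season(kernel, rng)
        nd, nh, nu = ibm.counts()
        count_rows.append({"t": t, "N": ibm.n, "n_d": nd, "n_h": nh, "n_u": nu,
                           "ratio": (nh + nu) / nd if nd else 0.0})
        ibm, events = ibm_step(ibm, kernel, intercepts, cfg, rng)
        events.insert(0, "season", t)
        for mid in events.loc[events["mother_id"] >= 0, "mother_id"]:
            offspring[int(mid)] = offspring.get(int(mid), 0) + 1
        dead = events.loc[(events["alive"] == 0), "id"]
        died.update(int(i) for i in dead)
        for i in events.loc[events["mother_id"] >= 0, "id"]:
            offspring.setdefault(int(i), 0)
        if collect_records:
            all_events.append(events)
        if ibm.n == 0:
            break

    lrs = pd.DataFrame(
        {"id": sorted(died), "lrs": [offspring.get(i, 0) for i in sorted(died)]}
    )
    return IBMRun(
        counts=pd.DataFrame(count_rows),
        records=pd.concat(all_events, ignore_index=True) if all_events else pd.DataFrame(),
        lrs=lrs,
    )


# ---------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------

@dataclass
class PPCResult:
    """Artificial-dataset summaries and their comparison with observations."""

    summaries: pd.DataFrame
    comparison: pd.DataFrame | None = None


def posterior_predictive_check(kernels, config: ModelConfig,
                               n_datasets: int = 1000, n_seasons: int = 40,
                               mask_fraction: float = 0.1,
                               rng: np.random.Generator | int | None = None,
                               observed: dict[str, float] | None = None,
                               spin_up: int = 20) -> PPCResult:
    """Generate artificial datasets from parameter draws and summarise them.

    ``kernels`` is a sequence of parameter draws (one seasonal kernel
    per draw — posterior samples or synthetic truth replicates); each
    artificial dataset simulates ``n_seasons`` seasons with one drawn
    kernel after a short demographic spin-up, randomly masks
    ``mask_fraction`` of the observation rows (they drop out of the
    summaries, mimicking seasons without behavioural data), and records
    density summaries of total size, subordinate counts and
    per-individual LRS. If ``observed`` supplies reference metrics
    (keys matching summary columns), the returned comparison reports
    the predictive quantile of each observation.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    kernels = list(kernels)
    rows = []
    for i in range(n_datasets):
        kernel = kernels[int(rng.integers(len(kernels)))]
        run = run_ibm(kernel, config, n_steps=spin_up + n_seasons, rng=rng)
        counts = run.counts.iloc[spin_up:]
        rec = run.records[run.records["season"] >= spin_up]
        if mask_fraction > 0 and len(rec):
            keep = rng.random(len(rec)) >= mask_fraction
            rec = rec[keep]
        lrs = run.lrs["lrs"].to_numpy()
        sub = rec[rec["stage"].isin(["h", "u"])]
        rows.append({
            "dataset": i,
            "mean_N": counts["N"].mean(),
            "mean_subordinates": (counts["n_h"] + counts["n_u"]).mean(),
            "min_subordinates": (counts["n_h"] + counts["n_u"]).min(),
            "max_subordinates": (counts["n_h"] + counts["n_u"]).max(),
            "helper_fraction": (sub["stage"] == "h").mean() if len(sub) else np.nan,
            "lrs_mean": lrs.mean() if lrs.size else np.nan,
            "lrs_zero_fraction": (lrs == 0).mean() if lrs.size else np.nan,
            "lrs_median": np.median(lrs) if lrs.size else np.nan,
        })
    summaries = pd.DataFrame(rows)

    comparison = None
    if observed:
        comp_rows = []
        for key, value in observed.items():
            if key not in summaries.columns:
                raise KeyError(f"observed metric {key!r} has no matching summary column")
            col = summaries[key].dropna().to_numpy()
            comp_rows.append({
                "metric": key, "observed": value,
                "predictive_mean": col.mean(),
                "predictive_quantile": float(np.mean(col <= value)),
            })
        comparison = pd.DataFrame(comp_rows)
    return PPCResult(summaries=summaries, comparison=comparison)
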