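"""Retrospective (LTRE) and prospective (elasticity) perturbation analyses.

The life table response experiment with a random design asks which
time-varying parameters drive the variance of the stochastic mean
population size: every post-burn-in step pairs the jointly drawn
intercept vector with the population size it produced, and a random
forest attributes response variance to the six intercept channels. A
linearised approximation — common-random-number finite-difference
sensitivities scaled by the season-level standard deviations — is
computed alongside as a cross-check.

Elasticities measure the proportional response of the stochastic mean
population size to proportional changes in a parameter, with paired
simulations sharing one random sequence (common random numbers).
Because logit-scale intercepts can be negative, the "proportional
change" contract is exactly ``x -> x * (1 + delta)`` on the stored
parameter value; the sign of an elasticity therefore follows the sign
of the parameter being scaled.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .config import ModelConfig
from .projection import simulate
from .rates import CHANNELS, SeasonalParameterKernel

__all__ = [
    "LTREResult",
    "ElasticityResult",
    "ltre_random_design",
    "elasticity",
    "elasticity_table",
    "ELASTICITY_CHANNELS",
]

#: Perturbable parameter channels for the elasticity analysis: the six
#: seasonal intercept channels, the fixed help-probability intercept and
#: the helper-presence contrast in dominant reproduction.
ELASTICITY_CHANNELS: tuple[str, ...] = CHANNELS + ("p_help_intercept", "R_d_q")


@dataclass
class LTREResult:
    """Variance attribution of the stochastic mean population size."""

    importance: pd.Series             # % per intercept channel (tree ensemble)
    variance_explained: float         # out-of-bag R^2 of the ensemble
    analytic_importance: pd.Series    # % from linearised sensitivities
    sensitivity_mu: pd.Series         # dN-hat / d(mean intercept)
    sensitivity_sigma: pd.Series      # dN-hat / d(among-season sd)


def ltre_random_design(kernel: SeasonalParameterKernel, config: ModelConfig,
                       rng: np.random.Generator | int | None = None,
                       n_trees: int = 500,
                       response: str = "per_step") -> LTREResult:
    """Random-design LTRE of the mean population size.

    ``response='per_step'`` (default) regresses the next-step total
    population size on the intercept vector drawn at each post-burn-in
    step, capturing the step-level environmental response.
    ``response='per_block'`` averages both over non-overlapping 20-step
    blocks, a coarser run-level variant.

    Importances are the ensemble's variance-reduction importances
    normalised to percentages; they are invariant to channel
    relabelling and to affine rescaling of the response.
    """
    if response not in ("per_step", "per_block"):
        raise ValueError("response must be 'per_step' or 'per_block'")
    sds = kernel.intercepts.std(axis=0, ddof=1).fillna(0.0)
    if np.all(sds.to_numpy() <= 0):
        raise ValueError("no intercept channel has among-season variance; LTRE is undefined")

    seed = int(np.random.default_rng(rng).integers(2**31 - 1))
    result = simulate(kernel, config, rng=seed, store_states=False)
    summary = result.summary
    y_full = summary["N"].shift(-1)
    y_full.iloc[-1] = result.final_state.total
    post = summary["t"] >= config.burn_in
    X = summary.loc[post, [f"b0_{ch}" for ch in CHANNELS]].to_numpy()
    y = y_full[post].to_numpy()
    if response == "per_block":
        nb = len(y) // 20
        X = X[: nb * 20].reshape(nb, 20, -1).mean(axis=1)
        y = y[: nb * 20].reshape(nb, 20).mean(axis=1)

    forest = RandomForestRegressor(
        n_estimators=n_trees, oob_score=True, random_state=seed % (2**31),
        n_jobs=1,
    )
    forest.fit(X, y)
    importance = pd.Series(100.0 * forest.feature_importances_, index=list(CHANNELS))

    # linearised cross-check: CRN finite differences with step eps^(1/3) * sd
    eps3 = np.finfo(float).eps ** (1.0 / 3.0)
    nhat_base = result.mean_population_size
    sens_mu, sens_sigma, contrib = {}, {}, {}
    for ch in CHANNELS:
        sd_c = float(sds[ch])
        if sd_c <= 0:          # constant channel: no stochastic contribution
            sens_mu[ch] = 0.0
            sens_sigma[ch] = 0.0
            contrib[ch] = 0.0
            continue
        delta = eps3 * sd_c
        k_mu = copy.deepcopy(kernel)
        k_mu.intercepts[ch] = k_mu.intercepts[ch] + delta
        nhat_mu = simulate(k_mu, config, rng=seed, store_states=False).mean_population_size
        sens_mu[ch] = (nhat_mu - nhat_base) / delta

        k_sd = copy.deepcopy(kernel)
        mu_c = k_sd.intercepts[ch].mean()
        k_sd.intercepts[ch] = mu_c + (1 + eps3) * (k_sd.intercepts[ch] - mu_c)
        nhat_sd = simulate(k_sd, config, rng=seed, store_states=False).mean_population_size
        sens_sigma[ch] = (nhat_sd - nhat_base) / (eps3 * sd_c)
        contrib[ch] = (sens_mu[ch] * sd_c) ** 2
    total = sum(contrib.values())
    analytic = pd.Series({ch: 100.0 * contrib[ch] / total for ch in CHANNELS})

    return LTREResult(
        importance=importance,
        variance_explained=float(forest.oob_score_),
        analytic_importance=analytic,
        sensitivity_mu=pd.Series(sens_mu),
        sensitivity_sigma=pd.Series(sens_sigma),
    )


# ---------------------------------------------------------------------
# elasticity
# ---------------------------------------------------------------------

@dataclass
class ElasticityResult:
    channel: str
    delta: float
    value: float
    nhat_base: float
    nhat_perturbed: float


def _perturbed_kernel(kernel: SeasonalParameterKernel, channel: str,
                      delta: float) -> SeasonalParameterKernel:
    k = copy.deepcopy(kernel)
    if channel in CHANNELS:
        k.intercepts[channel] = k.intercepts[channel] * (1.0 + delta)
    elif channel == "p_help_intercept":
        k.slopes["p_help"].intercept = k.slopes["p_help"].intercept * (1.0 + delta)
    elif channel == "R_d_q":
        k.slopes["R_d"].slopes["q"] = k.slopes["R_d"].slopes["q"] * (1.0 + delta)
    else:
        raise ValueError(f"unknown elasticity channel {channel!r}; "
                         f"choose from {ELASTICITY_CHANNELS}")
    return k


def elasticity(kernel: SeasonalParameterKernel, config: ModelConfig,
               channel: str, delta: float = 0.01,
               rng: np.random.Generator | int | None = None,
               common_random_numbers: bool = True) -> ElasticityResult:
    """Proportional sensitivity of the stochastic mean population size.

    Scales the chosen parameter by ``1 + delta`` and returns
    ``[log N-hat(perturbed) - log N-hat(base)] / log(1 + delta)`` from a
    pair of simulations. With ``common_random_numbers`` both runs share
    one seasonal draw sequence, which removes most Monte-Carlo noise
    from the difference; disabling it (used for variance comparisons)
    draws the two runs independently.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seed_base = int(rng.integers(2**31 - 1))
    seed_pert = seed_base if common_random_numbers else int(rng.integers(2**31 - 1))
    nhat_base = simulate(kernel, config, rng=seed_base, store_states=False).mean_population_size
    k_pert = _perturbed_kernel(kernel, channel, delta)
    nhat_pert = simulate(k_pert, config, rng=seed_pert, store_states=False).mean_population_size
    if nhat_base <= 0 or nhat_pert <= 0:
        raise ValueError("mean population size is zero in one of the paired runs")
    value = (np.log(nhat_pert) - np.log(nhat_base)) / np.log1p(delta)
    return ElasticityResult(channel=channel, delta=delta, value=float(value),
                            nhat_base=nhat_base, nhat_perturbed=nhat_pert)


def elasticity_table(kernel: SeasonalParameterKernel, config: ModelConfig,
                     channels=ELASTICITY_CHANNELS, delta: float = 0.01,
                     rng: np.random.Generator | int | None = None) -> pd.Series:
    """Elasticities for several channels, each from a CRN-paired run."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seed = int(rng.integers(2**31 - 1))
    return pd.Series({
        ch: elasticity(kernel, config, ch, delta=delta, rng=seed).value
        for ch in channels
    })
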