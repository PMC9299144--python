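"""Weighted-lottery acquisition of vacant dominant territories.

Surviving subordinates compete for the ``x`` territories left vacant by
dominant mortality. Helpers carry weight ``exp(beta)``, non-helpers
weight 1, so conditional on survival

    g_u = min(1, x / (exp(beta)*nh + nu)),
    g_h = min(1, exp(beta) * x / (exp(beta)*nh + nu)),

where ``nh`` and ``nu`` are the surviving helper and non-helper totals.
Whenever neither cap binds the allocation is conservative:
``g_h*nh + g_u*nu == x`` exactly. ``beta`` is estimated from
individual transition records by maximum likelihood on the Bernoulli
model with success probabilities ``p_h``/``p_u`` of the same form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "LotteryState",
    "BetaFit",
    "transition_probs",
    "vacancy_count",
    "fit_beta",
    "make_record_frame",
]

#: Canonical columns of a transition-record table.
RECORD_COLUMNS = ("season", "stage", "x", "nh", "nu", "outcome")


@dataclass
class LotteryState:
    """Expected vacancies and surviving claimants at one time step."""

    vacancies_x: float
    surviving_helpers_nh: float
    surviving_nonhelpers_nu: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("vacancies_x", "surviving_helpers_nh", "surviving_nonhelpers_nu"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def transition_probs(state: LotteryState) -> tuple[float, float]:
    """Per-capita probabilities ``(g_h, g_u)`` of acquiring dominance.

    Each probability is capped at 1 independently; with no claimants
    the pair is defined as ``(0, 0)`` (a warning is logged if vacancies
    then go unfilled).
    """
    w = np.exp(state.beta)
    denom = w * state.surviving_helpers_nh + state.surviving_nonhelpers_nu
    if denom <= 0:
        if state.vacancies_x > 0:
            logger.warning(
                "lottery with %g vacancies but no surviving claimants", state.vacancies_x
            )
        return 0.0, 0.0
    g_u_uncapped = state.vacancies_x / denom
    g_u = min(1.0, g_u_uncapped)
    g_h = min(1.0, w * g_u_uncapped)
    if g_u_uncapped > 1.0 or w * g_u_uncapped > 1.0:
        shortfall = state.vacancies_x - (
            g_h * state.surviving_helpers_nh + g_u * state.surviving_nonhelpers_nu
        )
        logger.warning(
            "lottery cap binding: %g of %g vacancies unfilled", shortfall, state.vacancies_x
        )
    return g_h, g_u


def vacancy_count(termax: float, surviving_dominants: float | np.ndarray) -> float:
    """Vacant territories: capacity minus summed surviving dominants, floored at 0."""
    if termax <= 0:
        raise ValueError("termax must be positive")
    return max(0.0, float(termax) - float(np.sum(surviving_dominants)))


# ---------------------------------------------------------------------
# maximum-likelihood fit of beta
# ---------------------------------------------------------------------

@dataclass
class BetaFit:
    """Result of the lottery-contrast fit."""

    beta: float
    se: float
    ci: tuple[float, float]
    loglik: float
    n: int

    def covers(self, value: float) -> bool:
        return self.ci[0] <= value <= self.ci[1]


def make_record_frame(stage, x, nh, nu, outcome, season=None) -> pd.DataFrame:
    """Assemble a transition-record table with the canonical columns."""
    n = len(stage)
    return pd.DataFrame(
        {
            "season": season if season is not None else np.zeros(n, dtype=int),
            "stage": stage,
            "x": x,
            "nh": nh,
            "nu": nu,
            "outcome": outcome,
        }
    )


def _success_probs(beta: float, is_helper: np.ndarray, x: np.ndarray,
                   nh: np.ndarray, nu: np.ndarray) -> np.ndarray:
    w = np.exp(beta)
    base = x / (w * nh + nu)
    p = np.where(is_helper, np.minimum(1.0, w * base), np.minimum(1.0, base))
    return p


def _neg_loglik(beta: float, is_helper, x, nh, nu, y) -> float:
    p = np.clip(_success_probs(beta, is_helper, x, nh, nu), 1e-12, 1 - 1e-12)
    return -float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def fit_beta(records: pd.DataFrame) -> BetaFit:
    """Maximum-likelihood estimate of the lottery contrast ``beta``.

    ``records`` needs columns ``stage`` ('helper'/'non-helper'), ``x``,
    ``nh``, ``nu`` and binary ``outcome``. Returns the MLE with a Wald
    95% interval from the numerical Hessian of the log-likelihood.

    Raises
    ------
    ValueError
        If the records lack one of the stages or one of the outcomes,
        if the likelihood is flat in ``beta`` (all records capped,
        "everyone wins"), or if the optimiser fails to converge.
    """
    is_helper = records["stage"].astype(str).str.lower().str.startswith("h").to_numpy()
    y = records["outcome"].to_numpy(dtype=float)
    if not (np.any(is_helper) and np.any(~is_helper)):
        raise ValueError("records must contain both helper and non-helper rows")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("records must contain both outcomes (0 and 1)")
    x = records["x"].to_numpy(dtype=float)
    nh = records["nh"].to_numpy(dtype=float)
    nu = records["nu"].to_numpy(dtype=float)
    if np.any(nh + nu < 1):
        raise ValueError("each record needs at least one claimant (nh + nu >= 1)")

    args = (is_helper, x, nh, nu, y)
    res = optimize.minimize_scalar(
        _neg_loglik, bounds=(-10.0, 10.0), args=args, method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise ValueError(f"beta fit did not converge: {res.message}")
    beta_hat = float(res.x)

    # numerical Hessian (second central difference)
    h = 1e-4
    f0 = _neg_loglik(beta_hat, *args)
    hess = (_neg_loglik(beta_hat + h, *args) - 2 * f0 + _neg_loglik(beta_hat - h, *args)) / h**2
    if not np.isfinite(hess) or hess <= 1e-8:
        raise ValueError(
            "likelihood is flat in beta (no curvature at the optimum); "
            "this happens when every record is capped, e.g. x >= nh + nu everywhere"
        )
    if abs(beta_hat) > 9.5:
        raise ValueError(
            f"beta estimate ran to the search boundary ({beta_hat:.2f}); "
            "the data may be separated or uninformative"
        )
    se = float(1.0 / np.sqrt(hess))
    ci = (beta_hat - 1.959963984540054 * se, beta_hat + 1.959963984540054 * se)
    return BetaFit(beta=beta_hat, se=se, ci=ci, loglik=-f0, n=len(records))
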