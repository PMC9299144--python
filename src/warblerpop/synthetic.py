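"""Synthetic inputs with known truth: seasonal kernels, lottery records, masking.

The generator emulates the two data products the pipeline consumes:

1. a seasonal parameter kernel — per-season logit intercepts for the six
   time-varying vital rates drawn from a multivariate normal with
   configurable among-season standard deviations and cross-channel
   correlation, plus fixed slopes;
2. individual territory-lottery transition records (one row per
   subordinate-season) generated from a known contrast ``beta``, for
   recovery fits; with optional masking of the behavioural stage label
   to mimic missing field classifications.

The default calibration targets the published scale of the study system
(about 111 dominant territories, roughly 50 helpers and 12 non-helpers,
half-year adult survival near 0.92 so annual survival near 0.84, a help
probability peaking at age 10, and dominant reproduction that rises and
falls with age unless a helper is present).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rates import CHANNELS, RateFunctionSpec, SeasonalParameterKernel

__all__ = [
    "SyntheticKernelSpec",
    "default_slopes",
    "default_help_spec",
    "default_kernel_spec",
    "default_kernel",
    "make_kernel",
    "make_transition_records",
    "mask_status",
]


def default_slopes() -> dict[str, RateFunctionSpec]:
    """Paper-shaped default term compositions for every rate function.

    * ``S_d``: cubic in age — flat high survival until ~9 years, then a
      senescent decline.
    * ``S_h`` / ``S_u``: shared slope values (subordinate survival is
      identical between the tactics), declining with age and with
      standardised population size; the two stages keep separate
      seasonal intercept channels for perturbation analyses.
    * ``R_d``: quadratic in age plus density dependence; the
      helper-presence interactions cancel the age terms, so reproduction
      of a helped dominant is age-constant and elevated.
    * ``R_h``: low co-breeding success, quadratic in age, density
      dependent.
    * ``f``: probability an offspring becomes a helper, increasing with
      the mother's age, density dependent.
    * ``p_help``: non-seasonal; quadratic in age with its peak at 10
      years, increasing in the subordinate ratio.
    """
    return {
        "S_d": RateFunctionSpec("S_d", {"a": 0.25, "a2": -0.02, "a3": -0.001}),
        "S_h": RateFunctionSpec("S_h", {"a": -0.12, "N": -0.25}),
        "S_u": RateFunctionSpec("S_u", {"a": -0.12, "N": -0.25}),
        "R_d": RateFunctionSpec(
            "R_d",
            {"a": 0.5, "a2": -0.04, "N": -0.15, "q": 2.0, "q_a": -0.5, "q_a2": 0.04},
        ),
        "R_h": RateFunctionSpec("R_h", {"a": 0.5, "a2": -0.04, "N": -0.15}),
        "f": RateFunctionSpec("f", {"a": 0.15, "N": -0.1}),
        "p_help": default_help_spec(),
    }


def default_help_spec() -> RateFunctionSpec:
    """Help probability: peak at age ``-b_a / (2 b_a2) = 10``; increasing in r."""
    return RateFunctionSpec(
        "p_help", {"a": 0.4, "a2": -0.02, "r": 0.5}, seasonal=False, intercept=-1.5
    )


@dataclass
class SyntheticKernelSpec:
    """Moments of the among-season intercept distribution.

    ``means``/``sds`` map each channel to the mean and among-season sd
    of its logit intercept; ``correlation`` is the 6x6 cross-channel
    correlation matrix (channel order :data:`~warblerpop.rates.CHANNELS`).
    The default correlation is the identity except for a 0.9 correlation
    between the helper and non-helper survival channels, which share one
    biological survival process but keep separate perturbation channels.
    """

    n_seasons: int = 40
    means: dict[str, float] = field(default_factory=lambda: {
        "S_d": 2.2, "S_h": 2.6, "S_u": 2.6, "R_d": -3.8, "R_h": -4.0, "f": 0.3,
    })
    sds: dict[str, float] = field(default_factory=lambda: {
        "S_d": 0.35, "S_h": 0.12, "S_u": 0.12, "R_d": 0.5, "R_h": 0.2, "f": 0.15,
    })
    correlation: np.ndarray | None = None
    slopes: dict[str, RateFunctionSpec] | None = None
    standardisation: tuple[float, float] = (170.0, 20.0)

    def __post_init__(self) -> None:
        if self.correlation is None:
            c = np.eye(len(CHANNELS))
            i_h, i_u = CHANNELS.index("S_h"), CHANNELS.index("S_u")
            c[i_h, i_u] = c[i_u, i_h] = 0.9
            self.correlation = c
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.correlation.shape != (len(CHANNELS), len(CHANNELS)):
            raise ValueError("correlation matrix must be 6x6 in channel order")
        if np.any(np.array([self.sds[c] for c in CHANNELS]) < 0):
            raise ValueError("among-season sds must be >= 0")
        if np.min(np.linalg.eigvalsh((self.correlation + self.correlation.T) / 2)) < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")


def default_kernel_spec(**overrides) -> SyntheticKernelSpec:
    return SyntheticKernelSpec(**overrides)


def make_kernel(spec: SyntheticKernelSpec,
                rng: np.random.Generator | int | None = None) -> SeasonalParameterKernel:
    """Draw a seasonal kernel from the spec's multivariate-normal moments."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mu = np.array([spec.means[c] for c in CHANNELS])
    sd = np.array([spec.sds[c] for c in CHANNELS])
    cov = spec.correlation * np.outer(sd, sd)
    draws = rng.multivariate_normal(mu, cov, size=spec.n_seasons, method="svd")
    table = pd.DataFrame(draws, columns=list(CHANNELS),
                         index=pd.Index(range(spec.n_seasons), name="season"))
    slopes = spec.slopes if spec.slopes is not None else default_slopes()
    return SeasonalParameterKernel(intercepts=table, slopes=slopes,
                                   standardisation=spec.standardisation)


def default_kernel(seed: int | None = 0) -> SeasonalParameterKernel:
    """Convenience: a 40-season kernel at the default calibration."""
    return make_kernel(default_kernel_spec(), np.random.default_rng(seed))


# ---------------------------------------------------------------------
# lottery transition records
# ---------------------------------------------------------------------

def make_transition_records(true_beta: float, n_records: int = 648,
                            rng: np.random.Generator | int | None = None,
                            *, nh_range: tuple[int, int] = (30, 60),
                            nu_range: tuple[int, int] = (8, 18),
                            x_range: tuple[int, int] = (3, 14)) -> pd.DataFrame:
    """Simulate per-individual lottery outcomes under a known ``beta``.

    Seasons are generated with helper pools much larger than non-helper
    pools (as in the study system); each surviving subordinate's outcome
    is a Bernoulli draw at the capped lottery probability of its stage.
    Returns a table with columns (season, stage, x, nh, nu, outcome)
    truncated to ``n_records`` rows.
    """
    if n_records < 100:
        raise ValueError("need at least 100 records for a meaningful fit")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    w = np.exp(true_beta)
    rows: list[dict] = []
    season = 0
    while len(rows) < n_records:
        nh = int(rng.integers(*nh_range))
        nu = int(rng.integers(*nu_range))
        x = int(rng.integers(*x_range))
        base = x / (w * nh + nu)
        p_h = min(1.0, w * base)
        p_u = min(1.0, base)
        for stage, n, p in (("helper", nh, p_h), ("non-helper", nu, p_u)):
            outcomes = rng.random(n) < p
            rows.extend(
                {"season": season, "stage": stage, "x": x, "nh": nh, "nu": nu,
                 "outcome": int(o)}
                for o in outcomes
            )
        season += 1
    df = pd.DataFrame(rows[:n_records])
    return df


def mask_status(records: pd.DataFrame, fraction: float,
                rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Hide the helper/non-helper label on a fraction of subordinate rows.

    Mimics subordinate-seasons with no behavioural observations: the
    ``stage`` entry of the selected rows becomes missing (``pd.NA``).
    Exactly ``round(fraction * n_subordinate_rows)`` rows are masked,
    chosen without replacement, reproducibly by seed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = records.copy()
    sub_idx = out.index[out["stage"].isin(["helper", "non-helper"])]
    k = int(round(fraction * len(sub_idx)))
    if k > 0:
        chosen = rng.choice(sub_idx.to_numpy(), size=k, replace=False)
        out.loc[chosen, "stage"] = pd.NA
    return out
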