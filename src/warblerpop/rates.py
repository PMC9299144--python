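"""Demographic probability functions of the life cycle.

Every time-varying vital rate (survival of dominants ``S_d``, of helpers
``S_h`` and non-helpers ``S_u``; reproduction of dominants ``R_d`` and
helpers ``R_h``; the probability ``f`` that an offspring enters the
population as a helper) is a logistic function of covariates,

    p = expit(b0_t + b1*x1 + ... + bn*xn),

where the intercept ``b0_t`` is drawn per season and the slopes are fixed.
The probability ``p_help`` that a dominant receives help is the one
non-seasonal function: it carries a single fixed intercept.

Covariate transforms are named by short labels:

=========  ==========================================
label      transform
=========  ==========================================
``a``      age (years)
``a2``     age squared
``a3``     age cubed
``N``      standardised population size
``q``      helper presence in the territory (0/1)
``q_a``    interaction q x age
``q_a2``   interaction q x age squared
``r``      subordinate-to-dominant ratio
=========  ==========================================
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import ModelConfig

__all__ = [
    "CHANNELS",
    "Covariates",
    "RateFunctionSpec",
    "SeasonalParameterKernel",
    "RateProfile",
    "logistic_rate",
    "help_probability",
    "rate_profile",
]

#: Seasonal intercept channels, in canonical column order.
CHANNELS: tuple[str, ...] = ("S_d", "S_h", "S_u", "R_d", "R_h", "f")

_TERM_TRANSFORMS: dict[str, Callable] = {
    "a": lambda c: c["a"],
    "a2": lambda c: c["a"] ** 2,
    "a3": lambda c: c["a"] ** 3,
    "N": lambda c: c["N"],
    "q": lambda c: c["q"],
    "q_a": lambda c: c["q"] * c["a"],
    "q_a2": lambda c: c["q"] * c["a"] ** 2,
    "r": lambda c: c["r"],
}

_TERM_COVARIATE = {"a": "a", "a2": "a", "a3": "a", "N": "N",
                   "q": "q", "q_a": "q", "q_a2": "q", "r": "r"}


@dataclass
class Covariates:
    """State-level covariates entering the rate functions.

    ``age`` runs on the half-year grid; ``pop_size_std`` is the raw count
    minus the standardisation mean, divided by the standardisation sd;
    ``ratio`` is subordinates over dominants; ``helper_presence`` is 0/1.
    """

    age: float | np.ndarray | None = None
    pop_size_std: float | None = None
    ratio: float | None = None
    helper_presence: float | None = None

    def as_dict(self) -> dict:
        out = {}
        if self.age is not None:
            out["a"] = np.asarray(self.age, dtype=float)
        if self.pop_size_std is not None:
            out["N"] = self.pop_size_std
        if self.ratio is not None:
            out["r"] = self.ratio
        if self.helper_presence is not None:
            out["q"] = self.helper_presence
        return out


@dataclass
class RateFunctionSpec:
    """One demographic function: named slopes plus a seasonality flag.

    ``slopes`` maps term labels (see module docstring) to slope values.
    A seasonal spec takes its intercept from the kernel row of the drawn
    season; a non-seasonal spec (only ``p_help``) carries ``intercept``.
    """

    name: str
    slopes: dict[str, float] = field(default_factory=dict)
    seasonal: bool = True
    intercept: float | None = None

    def __post_init__(self) -> None:
        unknown = set(self.slopes) - set(_TERM_TRANSFORMS)
        if unknown:
            raise ValueError(f"unknown term label(s) {sorted(unknown)} in spec {self.name!r}")
        for term, slope in self.slopes.items():
            if not np.isfinite(slope):
                raise ValueError(f"non-finite slope for term {term!r} in spec {self.name!r}")
        if not self.seasonal and self.intercept is None:
            raise ValueError(f"non-seasonal spec {self.name!r} needs a fixed intercept")

    def linear_predictor(self, intercept: float, cov: Mapping[str, object]) -> np.ndarray:
        eta = np.asarray(intercept, dtype=float)
        for term, slope in self.slopes.items():
            needed = _TERM_COVARIATE[term]
            if needed not in cov:
                raise ValueError(
                    f"rate function {self.name!r} needs covariate {needed!r} for term {term!r}"
                )
            eta = eta + slope * np.asarray(_TERM_TRANSFORMS[term](cov), dtype=float)
        if not np.all(np.isfinite(eta)):
            raise ValueError(f"non-finite linear predictor in rate function {self.name!r}")
        return eta


def logistic_rate(spec: RateFunctionSpec, intercept: float,
                  cov: Covariates | Mapping[str, object]) -> np.ndarray:
    """Evaluate one logistic rate: expit(intercept + sum slope_i * term_i).

    ``cov`` may be a :class:`Covariates` or a plain mapping with keys
    ``a``, ``N``, ``q``, ``r``. Returns probabilities strictly in (0, 1).
    """
    c = cov.as_dict() if isinstance(cov, Covariates) else dict(cov)
    return expit(spec.linear_predictor(intercept, c))


def help_probability(age, ratio, spec: RateFunctionSpec | None = None) -> np.ndarray:
    """Probability that a dominant of the given age receives help.

    Quadratic in the dominant's age and increasing in the subordinate
    ratio ``r`` under the default parameterisation; a single fixed
    intercept (the function does not vary between seasons).
    """
    if spec is None:
        from .synthetic import default_help_spec
        spec = default_help_spec()
    if np.any(np.asarray(ratio) < 0):
        raise ValueError("subordinate ratio r must be non-negative")
    return logistic_rate(spec, spec.intercept, {"a": np.asarray(age, float), "r": ratio})


@dataclass
class SeasonalParameterKernel:
    """Empirical kernel of per-season intercepts plus fixed slopes.

    ``intercepts`` is a season x channel table (columns exactly
    :data:`CHANNELS`); each stochastic step resamples one season row
    jointly across channels, preserving within-season covariance.
    ``slopes`` holds one :class:`RateFunctionSpec` per function,
    including the non-seasonal ``p_help``. ``standardisation`` is the
    (mean, sd) of the raw population size.
    """

    intercepts: pd.DataFrame
    slopes: dict[str, RateFunctionSpec]
    standardisation: tuple[float, float] = (170.0, 20.0)

    def __post_init__(self) -> None:
        missing = set(CHANNELS) - set(self.intercepts.columns)
        if missing:
            raise ValueError(f"kernel intercept table missing channel(s) {sorted(missing)}")
        self.intercepts = self.intercepts[list(CHANNELS)].astype(float)
        if self.intercepts.isna().any().any():
            raise ValueError("kernel intercept table contains missing values")
        if len(self.intercepts) == 0:
            raise ValueError("kernel must contain at least one season")
        if self.standardisation[1] <= 0:
            raise ValueError("standardisation sd must be positive")
        needed = set(CHANNELS) | {"p_help"}
        missing = needed - set(self.slopes)
        if missing:
            raise ValueError(f"kernel slopes missing function(s) {sorted(missing)}")

    # ----- basic accessors -------------------------------------------
    @property
    def seasons(self) -> list:
        return list(self.intercepts.index)

    @property
    def n_seasons(self) -> int:
        return len(self.intercepts)

    def intercept_vector(self, season) -> pd.Series:
        if season not in self.intercepts.index:
            raise KeyError(f"unknown season label {season!r}")
        return self.intercepts.loc[season]

    def mean_intercepts(self) -> pd.Series:
        return self.intercepts.mean(axis=0)

    def apply_standardisation(self, config: ModelConfig) -> ModelConfig:
        """Copy of ``config`` carrying this kernel's standardisation constants."""
        import dataclasses
        return dataclasses.replace(
            config,
            standardisation_mean=self.standardisation[0],
            standardisation_sd=self.standardisation[1],
        )

    # ----- CSV round trip --------------------------------------------
    def to_csv(self, intercepts_path: str | Path, slopes_path: str | Path) -> None:
        """Write the long-format intercepts and slopes tables.

        Intercepts: columns (season, function, value); slopes: columns
        (function, term, value) where the fixed intercept of a
        non-seasonal function is stored under term ``intercept``, and
        the standardisation constants under function ``standardisation``
        (terms ``mean`` / ``sd``).
        """
        long = self.intercepts.stack().rename("value").reset_index()
        long.columns = ["season", "function", "value"]
        long.to_csv(intercepts_path, index=False)

        rows = []
        for name, spec in self.slopes.items():
            for term, slope in spec.slopes.items():
                rows.append({"function": name, "term": term, "value": slope})
            if not spec.seasonal:
                rows.append({"function": name, "term": "intercept", "value": spec.intercept})
        rows.append({"function": "standardisation", "term": "mean", "value": self.standardisation[0]})
        rows.append({"function": "standardisation", "term": "sd", "value": self.standardisation[1]})
        pd.DataFrame(rows).to_csv(slopes_path, index=False)

    @classmethod
    def from_csv(cls, intercepts_path: str | Path, slopes_path: str | Path) -> "SeasonalParameterKernel":
        long = pd.read_csv(intercepts_path)
        table = long.pivot(index="season", columns="function", values="value")
        slopes_long = pd.read_csv(slopes_path)
        std = (170.0, 20.0)
        slopes: dict[str, RateFunctionSpec] = {}
        for name, grp in slopes_long.groupby("function"):
            if name == "standardisation":
                vals = dict(zip(grp["term"], grp["value"]))
                std = (float(vals["mean"]), float(vals["sd"]))
                continue
            terms = dict(zip(grp["term"], grp["value"]))
            intercept = terms.pop("intercept", None)
            seasonal = intercept is None
            slopes[name] = RateFunctionSpec(
                name=name, slopes={k: float(v) for k, v in terms.items()},
                seasonal=seasonal,
                intercept=None if seasonal else float(intercept),
            )
        return cls(intercepts=table, slopes=slopes, standardisation=std)


@dataclass
class RateProfile:
    """Per-(st)age probabilities for one season and one population state.

    Arrays are aligned with the config's age grids: dominant-indexed
    arrays (``S_d``, ``R_d_q0``, ``R_d_q1``, ``f_dom``, ``p_help``) with
    ``dom_ages``; subordinate-indexed arrays (``S_h``, ``S_u``, ``R_h``,
    ``f_sub``) with ``sub_ages``.
    """

    S_d: np.ndarray
    S_h: np.ndarray
    S_u: np.ndarray
    R_d_q0: np.ndarray
    R_d_q1: np.ndarray
    R_h: np.ndarray
    f_dom: np.ndarray
    f_sub: np.ndarray
    p_help: np.ndarray

    def as_frame(self, config: ModelConfig) -> pd.DataFrame:
        """Long-format table of every probability over the age grid."""
        rows = []
        for name in ("S_d", "R_d_q0", "R_d_q1", "f_dom", "p_help"):
            for a, v in zip(config.dom_ages, getattr(self, name)):
                rows.append({"function": name, "age": a, "value": v})
        for name in ("S_h", "S_u", "R_h", "f_sub"):
            for a, v in zip(config.sub_ages, getattr(self, name)):
                rows.append({"function": name, "age": a, "value": v})
        return pd.DataFrame(rows)


def rate_profile(kernel: SeasonalParameterKernel,
                 intercepts: Mapping[str, float] | pd.Series,
                 config: ModelConfig,
                 *, pop_size_raw: float, ratio: float) -> RateProfile:
    """Vectorise every rate function over the age grids for one step.

    ``intercepts`` is the jointly drawn per-season intercept vector
    (one entry per channel in :data:`CHANNELS`). The raw population
    size is standardised with the kernel's constants.
    """
    mean, sd = kernel.standardisation
    N = (float(pop_size_raw) - mean) / sd
    if ratio < 0:
        raise ValueError("subordinate ratio r must be non-negative")
    sub_a, dom_a = config.sub_ages, config.dom_ages

    def ev(name: str, ages: np.ndarray, q: float | None = None) -> np.ndarray:
        spec = kernel.slopes[name]
        cov = {"a": ages, "N": N, "r": ratio}
        if q is not None:
            cov["q"] = q
        b0 = spec.intercept if not spec.seasonal else float(intercepts[name])
        p = np.asarray(logistic_rate(spec, b0, cov), dtype=float)
        return np.broadcast_to(p, ages.shape).copy()   # age-free specs broadcast

    help_spec = kernel.slopes["p_help"]
    return RateProfile(
        S_d=ev("S_d", dom_a),
        S_h=ev("S_h", sub_a),
        S_u=ev("S_u", sub_a),
        R_d_q0=ev("R_d", dom_a, q=0.0),
        R_d_q1=ev("R_d", dom_a, q=1.0),
        R_h=ev("R_h", sub_a),
        f_dom=ev("f", dom_a),
        f_sub=ev("f", sub_a),
        p_help=np.broadcast_to(
            np.asarray(help_probability(dom_a, ratio, help_spec), dtype=float),
            dom_a.shape).copy(),
    )
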