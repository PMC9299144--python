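"""Model configuration and the half-year (st)age grids.

The life cycle is censused every half year. Subordinates (helpers and
non-helpers) occupy age classes ``step, 2*step, ..., age_max`` — offspring
enter the population at age ``step`` (0.5 years by default). Dominants have
no ``step`` class: a newly promoted subordinate of age ``a`` becomes a
dominant of age ``a + step``, so the dominant grid starts at ``2*step``
(1.0 years). The top age class is recursive: survivors of age ``age_max``
remain in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ModelConfig", "load_config", "save_config"]


@dataclass
class ModelConfig:
    """Fixed structural parameters of the projection model.

    Parameters
    ----------
    termax
        Maximum (mean observed) number of dominant territories; the
        model's carrying-capacity constraint. Non-integer values are
        allowed in the expected-value projection.
    beta
        Log-weight contrast of helpers versus non-helpers in the
        territory lottery (helpers carry weight ``exp(beta)``,
        non-helpers weight 1). Negative values disadvantage helpers.
    age_max
        Maximum age in years; the top class is recursive.
    step
        Census interval in years (half-year seasons).
    horizon
        Number of projection steps in a stochastic simulation.
    burn_in
        Leading steps discarded before computing stationary summaries.
    seed
        Default seed for the simulation RNG (overridable per call).
    standardisation_mean, standardisation_sd
        Mean and standard deviation used to standardise the raw
        population count before it enters the logistic rate functions.
        Stored here (not recomputed per run) so that simulated sizes
        outside the observed range extrapolate linearly on the logit
        scale. These defaults are overridden by the kernel's own
        values when a kernel carries them.
    extinction_tol
        Total density below which the population is declared extinct
        and the simulation truncated.
    """

    termax: float = 111.2
    beta: float = -0.549
    age_max: float = 15.0
    step: float = 0.5
    horizon: int = 10_000
    burn_in: int = 7_000
    seed: int | None = None
    standardisation_mean: float = 170.0
    standardisation_sd: float = 20.0
    extinction_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.termax <= 0:
            raise ValueError("termax must be positive")
        if self.burn_in >= self.horizon:
            raise ValueError("burn_in must be smaller than horizon")
        if self.step <= 0 or self.age_max < 2 * self.step:
            raise ValueError("need age_max >= 2*step > 0")

    # ----- age grids -------------------------------------------------
    @property
    def sub_ages(self) -> np.ndarray:
        """Subordinate (helper / non-helper) age grid: step .. age_max."""
        n = int(round(self.age_max / self.step))
        return self.step * np.arange(1, n + 1)

    @property
    def dom_ages(self) -> np.ndarray:
        """Dominant age grid: 2*step .. age_max."""
        n = int(round(self.age_max / self.step))
        return self.step * np.arange(2, n + 1)

    @property
    def n_sub(self) -> int:
        return self.sub_ages.size

    @property
    def n_dom(self) -> int:
        return self.dom_ages.size

    def standardise(self, raw_pop_size: float) -> float:
        """Standardise a raw population count for use as a covariate."""
        return (raw_pop_size - self.standardisation_mean) / self.standardisation_sd


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration to YAML."""
    d = asdict(config)
    # nest the standardisation block as documented in the file format
    d["standardisation"] = {
        "mean": d.pop("standardisation_mean"),
        "sd": d.pop("standardisation_sd"),
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: str | Path) -> ModelConfig:
    """Read a configuration from YAML (inverse of :func:`save_config`)."""
    d = yaml.safe_load(Path(path).read_text())
    std = d.pop("standardisation", None)
    if std is not None:
        d["standardisation_mean"] = float(std["mean"])
        d["standardisation_sd"] = float(std["sd"])
    return ModelConfig(**d)
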