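"""Shared fixtures: small kernels, configurations, and independent oracles."""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import pytest

import warblerpop as wp
from warblerpop.rates import CHANNELS, RateFunctionSpec, SeasonalParameterKernel

logging.getLogger("warblerpop").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_kernel():
    return wp.default_kernel(seed=0)


@pytest.fixture()
def short_config():
    return wp.ModelConfig(horizon=400, burn_in=200)


def constant_kernel(intercepts: dict[str, float],
                    slopes: dict[str, RateFunctionSpec] | None = None,
                    n_seasons: int = 1,
                    standardisation=(170.0, 20.0)) -> SeasonalParameterKernel:
    """Kernel with identical intercepts in every season (deterministic env)."""
    table = pd.DataFrame(
        {ch: [intercepts[ch]] * n_seasons for ch in CHANNELS},
        index=pd.Index(range(n_seasons), name="season"),
    )
    if slopes is None:
        slopes = wp.default_slopes()
    return SeasonalParameterKernel(intercepts=table, slopes=slopes,
                                   standardisation=standardisation)


def zero_slope_specs(help_intercept: float = 0.0) -> dict[str, RateFunctionSpec]:
    """Rate functions with no covariate effects: probability = expit(intercept)."""
    specs = {ch: RateFunctionSpec(ch, {}) for ch in CHANNELS}
    specs["p_help"] = RateFunctionSpec("p_help", {}, seasonal=False,
                                       intercept=help_intercept)
    return specs


# ---------------------------------------------------------------------
# independent single-step oracle (scalar arithmetic, no package code)
# ---------------------------------------------------------------------

def toy_step_oracle(d, h, u, pars, termax, beta, std_mean, std_sd):
    """Hand evaluation of one census step on the 3-age toy grid.

    Subordinate ages (0.5, 1.0, 1.5); dominant ages (1.0, 1.5); the top
    class of each grid is recursive. ``pars`` maps each function name to
    its scalar parameters. Written with explicit scalar arithmetic,
    independently of the package's vectorised implementation.
    """
    exp = math.exp

    def logi(eta):
        return 1.0 / (1.0 + exp(-eta))

    N = sum(d) + sum(h) + sum(u)
    Ns = (N - std_mean) / std_sd
    r = (sum(h) + sum(u)) / sum(d)
    sub_ages = [0.5, 1.0, 1.5]
    dom_ages = [1.0, 1.5]

    S_d = [logi(pars["S_d"]["b0"] + pars["S_d"]["a"] * a) for a in dom_ages]
    S_h = [logi(pars["S_h"]["b0"] + pars["S_h"]["a"] * a + pars["S_h"]["N"] * Ns)
           for a in sub_ages]
    S_u = [logi(pars["S_u"]["b0"] + pars["S_u"]["a"] * a + pars["S_u"]["N"] * Ns)
           for a in sub_ages]
    R_d0 = [logi(pars["R_d"]["b0"] + pars["R_d"]["a"] * a + pars["R_d"]["N"] * Ns)
            for a in dom_ages]
    R_d1 = [logi(pars["R_d"]["b0"] + pars["R_d"]["a"] * a + pars["R_d"]["N"] * Ns
                 + pars["R_d"]["q"] + pars["R_d"]["q_a"] * a) for a in dom_ages]
    R_h = [logi(pars["R_h"]["b0"] + pars["R_h"]["a"] * a) for a in sub_ages]
    f_sub = [logi(pars["f"]["b0"] + pars["f"]["a"] * a) for a in sub_ages]
    f_dom = [logi(pars["f"]["b0"] + pars["f"]["a"] * a) for a in dom_ages]
    p_hlp = [logi(pars["p_help"]["b0"] + pars["p_help"]["a"] * a
                  + pars["p_help"]["r"] * r) for a in dom_ages]

    surv_dom = [S_d[j] * d[j] for j in range(2)]
    x = max(0.0, termax - sum(surv_dom))
    w = exp(beta)
    sh = [S_h[i] * h[i] for i in range(3)]
    su = [S_u[i] * u[i] for i in range(3)]
    denom = w * sum(sh) + sum(su)
    g_u = min(1.0, x / denom)
    g_h = min(1.0, w * x / denom)

    # dominants: survivors age (top recursive); promoted subordinates enter at a+0.5
    nd = [0.0, 0.0]
    nd[1] += surv_dom[0]
    nd[1] += surv_dom[1]
    nd[0] += g_h * sh[0] + g_u * su[0]          # subordinates aged 0.5 -> dominant 1.0
    nd[1] += g_h * sh[1] + g_u * su[1]          # aged 1.0 -> 1.5
    nd[1] += g_h * sh[2] + g_u * su[2]          # aged 1.5 -> capped at 1.5

    nh = [0.0, 0.0, 0.0]
    nu = [0.0, 0.0, 0.0]
    nh[1] += (1 - g_h) * sh[0]
    nh[2] += (1 - g_h) * sh[1]
    nh[2] += (1 - g_h) * sh[2]
    nu[1] += (1 - g_u) * su[0]
    nu[2] += (1 - g_u) * su[1]
    nu[2] += (1 - g_u) * su[2]

    births_h = 0.0
    births_u = 0.0
    for i in range(3):
        b = R_h[i] * h[i]
        births_h += f_sub[i] * b
        births_u += (1 - f_sub[i]) * b
    for j in range(2):
        mix = p_hlp[j] * R_d1[j] + (1 - p_hlp[j]) * R_d0[j]
        b = mix * d[j]
        births_h += f_dom[j] * b
        births_u += (1 - f_dom[j]) * b
    nh[0] += births_h
    nu[0] += births_u
    return nd, nh, nu


def toy_kernel_and_config():
    """Package-side objects matching :func:`toy_step_oracle`'s parameterisation."""
    pars = {
        "S_d": {"b0": 1.2, "a": 0.1},
        "S_h": {"b0": 1.0, "a": -0.2, "N": -0.3},
        "S_u": {"b0": 0.9, "a": -0.15, "N": -0.25},
        "R_d": {"b0": -0.8, "a": 0.4, "N": -0.2, "q": 1.1, "q_a": -0.4},
        "R_h": {"b0": -1.5, "a": 0.3},
        "f": {"b0": 0.2, "a": 0.15},
        "p_help": {"b0": -0.6, "a": 0.25, "r": 0.45},
    }
    slopes = {
        "S_d": RateFunctionSpec("S_d", {"a": pars["S_d"]["a"]}),
        "S_h": RateFunctionSpec("S_h", {"a": pars["S_h"]["a"], "N": pars["S_h"]["N"]}),
        "S_u": RateFunctionSpec("S_u", {"a": pars["S_u"]["a"], "N": pars["S_u"]["N"]}),
        "R_d": RateFunctionSpec("R_d", {"a": pars["R_d"]["a"], "N": pars["R_d"]["N"],
                                        "q": pars["R_d"]["q"], "q_a": pars["R_d"]["q_a"]}),
        "R_h": RateFunctionSpec("R_h", {"a": pars["R_h"]["a"]}),
        "f": RateFunctionSpec("f", {"a": pars["f"]["a"]}),
        "p_help": RateFunctionSpec("p_help", {"a": pars["p_help"]["a"],
                                              "r": pars["p_help"]["r"]},
                                   seasonal=False, intercept=pars["p_help"]["b0"]),
    }
    intercepts = {ch: pars[ch]["b0"] for ch in CHANNELS}
    kernel = constant_kernel(intercepts, slopes=slopes, standardisation=(10.0, 4.0))
    config = wp.ModelConfig(termax=5.0, beta=-0.4, age_max=1.5, step=0.5,
                            horizon=10, burn_in=5,
                            standardisation_mean=10.0, standardisation_sd=4.0)
    return kernel, config, pars
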