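"""Shared fixtures and independent Monte Carlo oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import expit

from colliderbias import ScenarioConfig


@pytest.fixture
def small_cfg() -> ScenarioConfig:
    """A reduced-population headline scenario (strong selection, r = 0.30)."""
    return ScenarioConfig(
        r=0.30, gamma=0.0, or_p=1.8, or_o=1.8, n_population=200_000, n_reps=5, seed=11
    )


def mc_alpha_oracle(
    or_p: float,
    or_o: float,
    gamma: float,
    target: float,
    n_draws: int = 10_000_000,
    seed: int = 2024,
) -> float:
    """Monte Carlo oracle for the selection intercept.

    Draws (P, O) pairs from the bivariate Normal implied by ``gamma`` and
    root-finds alpha on the *empirical* mean selection probability.  Shares
    no code path with the package's quadrature calibration.
    """
    rng = np.random.default_rng(seed)
    p = rng.standard_normal(n_draws)
    o = gamma * p + math.sqrt(1.0 - gamma**2) * rng.standard_normal(n_draws)
    lin = math.log(or_p) * p + math.log(or_o) * o

    def frac(alpha: float) -> float:
        return float(expit(alpha + lin).mean()) - target

    return brentq(frac, -30.0, 10.0, xtol=1e-10)


def ols_slope_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple-regression slope and classical SE (textbook formulas)."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    beta = float(xc.dot(yc) / xc.dot(xc))
    resid = yc - beta * xc
    se = math.sqrt(resid.dot(resid) / (n - 2) / xc.dot(xc))
    return beta, se
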