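"""Calibration of the logistic selection intercept.

Selection follows a log-odds-linear model,

    Pr(S = 1 | covariates) = expit(alpha + sum_k ln(OR_k) * X_k),

with jointly Gaussian, mean-zero covariates.  The linear predictor
L = sum_k ln(OR_k) X_k is then itself Gaussian, L ~ N(0, sigma_L^2), so the
marginal selection probability reduces exactly to a one-dimensional
logistic-normal integral

    E[ expit(alpha + sigma_L * Z) ],  Z ~ N(0, 1),

which we evaluate with Gauss-Hermite quadrature and invert for alpha by
bracketed root-finding.  The baseline risk is thus controlled analytically:
the realized number selected is binomial around n * target_fraction.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import ConfigurationError, NumericalError

#: Number of Gauss-Hermite nodes; the integrand is smooth and bounded, and
#: 201 nodes leave the quadrature error far below the 1e-8 tolerance.
_N_NODES = 201

_nodes, _weights = np.polynomial.hermite_e.hermegauss(_N_NODES)
_weights = _weights / math.sqrt(2.0 * math.pi)


def linear_predictor_sd(or_p: float, or_o: float, gamma: float) -> float:
    """SD of ln(or_p)*P + ln(or_o)*O for unit-SD (P, O) with corr gamma."""
    bp, bo = math.log(or_p), math.log(or_o)
    var = bp * bp + bo * bo + 2.0 * gamma * bp * bo
    if var < 0.0:
        raise ConfigurationError("selection linear predictor has negative variance")
    return math.sqrt(var)


def selection_fraction(alpha: float, sigma_l: float) -> float:
    """Marginal selection probability E[expit(alpha + sigma_l * Z)], Z ~ N(0,1)."""
    return float(np.dot(_weights, expit(alpha + sigma_l * _nodes)))


def calibrate_intercept(
    or_p: float,
    or_o: float,
    gamma: float,
    target_fraction: float,
    tol: float = 1e-8,
) -> float:
    """Log-odds intercept alpha making the marginal selection probability hit target.

    Parameters
    ----------
    or_p, or_o
        Per-SD selection odds ratios for phenotype and outcome.
    gamma
        Phenotype-on-outcome coefficient; determines corr(P, O) = gamma for
        unit-SD variables and hence the variance of the linear predictor.
    target_fraction
        Desired marginal probability of selection, in (0, 1).
    tol
        Absolute tolerance on the achieved expectation.

    Returns
    -------
    float
        alpha with ``E[expit(alpha + ln(or_p) P + ln(or_o) O)] = target_fraction``.
    """
    if or_p <= 0.0 or or_o <= 0.0:
        raise ConfigurationError("odds ratios must be positive")
    sigma_l = linear_predictor_sd(or_p, or_o, gamma)
    return calibrate_intercept_for_sd(sigma_l, target_fraction, tol=tol)


def calibrate_intercept_for_sd(
    sigma_l: float, target_fraction: float, tol: float = 1e-8
) -> float:
    """Intercept for a Gaussian N(0, sigma_l^2) logistic linear predictor."""
    if not 0.0 < target_fraction < 1.0:
        raise ConfigurationError("target_fraction must be in (0, 1)")
    if sigma_l < 0.0:
        raise ConfigurationError("sigma_l must be non-negative")
    base = float(logit(target_fraction))
    if sigma_l == 0.0:
        return base
    # The expectation is strictly increasing in alpha; a +-(6 sigma_L + 2)
    # bracket around the no-covariate solution always straddles the root.
    lo, hi = base - 6.0 * sigma_l - 2.0, base + 6.0 * sigma_l + 2.0
    try:
        alpha = brentq(
            lambda a: selection_fraction(a, sigma_l) - target_fraction,
            lo,
            hi,
            xtol=1e-13,
            rtol=8.9e-16,
        )
    except ValueError as exc:  # pragma: no cover - bracket is constructed to hold
        raise NumericalError(
            f"intercept root-finding failed for sigma_l={sigma_l}, "
            f"target={target_fraction}: {exc}"
        ) from exc
    achieved = selection_fraction(alpha, sigma_l)
    if abs(achieved - target_fraction) > tol:
        raise NumericalError(
            f"calibration residual {achieved - target_fraction:.3e} exceeds tol={tol:g} "
            f"(alpha={alpha:.6f})"
        )
    return float(alpha)
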