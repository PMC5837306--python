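"""Deterministic large-sample limits of the selected-sample regression.

These are not Monte Carlo quantities: every moment of (P, O) conditional on
selection is a two-dimensional logistic-normal integral evaluated by
Gauss-Hermite quadrature, and the allele score enters through the exact
conditional law G | P, O ~ N(r P, 1 - r^2) (G is independent of O given P).
The module provides an independent, simulation-free route to the bias that
the Monte Carlo engine estimates, used for cross-checks and for mapping the
whole scenario grid cheaply.

Key identity: the infinite-population selected-sample OLS slope of O on G is

    beta_sel = r * Cov(P, O | S=1) / (1 - r^2 * (1 - Var(P | S=1)))

so the collider bias is driven entirely by the covariance that selection
induces between phenotype and outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .calibration import calibrate_intercept
from .config import ScenarioConfig

_N_NODES = 96
_x, _w = np.polynomial.hermite_e.hermegauss(_N_NODES)
_w = _w / math.sqrt(2.0 * math.pi)
_X, _Y = np.meshgrid(_x, _x, indexing="ij")
_W = np.outer(_w, _w)


@dataclass(frozen=True)
class SelectedMoments:
    """Large-sample moments of the selected sample for one scenario."""

    alpha: float
    fraction: float
    mean_p: float
    mean_o: float
    var_p: float
    var_o: float
    cov_po: float
    beta_selected: float      # plim of the selected-sample OLS slope of O on G
    beta_population: float    # gamma * r
    shift_p: float            # E[P | S=1] - E[P | S=0]
    shift_o: float
    se_infinite: float        # large-sample classical OLS standard error
    expected_z: float         # beta_selected / se at n_selected individuals

    @property
    def bias(self) -> float:
        return self.beta_selected - self.beta_population


def selected_moments(cfg: ScenarioConfig) -> SelectedMoments:
    """Quadrature evaluation of the selected-sample moments for ``cfg``.

    ``se_infinite`` and ``expected_z`` use the scenario's expected selected
    sample size ``n_population * target_fraction``.
    """
    gamma, r = cfg.gamma, cfg.r
    p = _X
    o = gamma * _X + math.sqrt(1.0 - gamma**2) * _Y
    alpha = calibrate_intercept(cfg.or_p, cfg.or_o, gamma, cfg.target_fraction)
    pi = expit(alpha + math.log(cfg.or_p) * p + math.log(cfg.or_o) * o)
    dens = _W * pi
    fraction = float(dens.sum())

    def e(q: np.ndarray) -> float:
        return float((dens * q).sum() / fraction)

    mean_p, mean_o = e(p), e(o)
    var_p = e(p * p) - mean_p**2
    var_o = e(o * o) - mean_o**2
    cov_po = e(p * o) - mean_p * mean_o

    # G | P, O depends on P only: E[G|P,O] = r P, Var(G|P,O) = 1 - r^2.
    cov_go = r * cov_po
    var_g = r * r * var_p + 1.0 - r * r
    beta_selected = cov_go / var_g

    resid_var = var_o - beta_selected**2 * var_g
    n_sel = cfg.n_population * cfg.target_fraction
    se = math.sqrt(resid_var / (n_sel * var_g))

    # E[P] = 0 unconditionally => fraction * E[P|S=1] + (1-fraction) * E[P|S=0] = 0.
    shift_p = mean_p - (-fraction * mean_p) / (1.0 - fraction)
    shift_o = mean_o - (-fraction * mean_o) / (1.0 - fraction)

    return SelectedMoments(
        alpha=alpha,
        fraction=fraction,
        mean_p=mean_p,
        mean_o=mean_o,
        var_p=var_p,
        var_o=var_o,
        cov_po=cov_po,
        beta_selected=float(beta_selected),
        beta_population=cfg.true_beta,
        shift_p=shift_p,
        shift_o=shift_o,
        se_infinite=se,
        expected_z=float(beta_selected / se),
    )
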