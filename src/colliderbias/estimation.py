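"""Regression fits in the intended and selected populations.

The analysis of interest is the unadjusted OLS regression of outcome on
allele score (not adjusting for phenotype), with classical standard errors
and 95% Wald intervals.  An inverse-probability-weighted variant reweights
selected individuals by 1 / Pr(S=1 | P, O) under the true selection model
and uses robust (sandwich) standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .errors import DegenerateSampleError, SingularDesignError
from .population import Population

#: Standard-normal 97.5% quantile used for 95% Wald intervals.
Z_CRIT = 1.959964


@dataclass(frozen=True)
class FitResult:
    """One regression fit: slope of outcome on allele score."""

    beta: float
    se: float
    z: float
    ci_low: float
    ci_high: float
    n_used: int

    def tsv_row(self) -> str:
        return (
            f"{self.beta:.6g}\t{self.se:.6g}\t{self.z:.6g}\t"
            f"{self.ci_low:.6g}\t{self.ci_high:.6g}\t{self.n_used}\n"
        )

    @staticmethod
    def tsv_header() -> str:
        return "beta\tse\tz\tci_low\tci_high\tn_used\n"

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(self.tsv_header() + self.tsv_row())


def _make_result(beta: float, se: float, n: int) -> FitResult:
    if se > 0.0:
        z = beta / se
    else:
        z = math.copysign(math.inf, beta) if beta != 0.0 else 0.0
    return FitResult(
        beta=float(beta),
        se=float(se),
        z=float(z),
        ci_low=float(beta - Z_CRIT * se),
        ci_high=float(beta + Z_CRIT * se),
        n_used=int(n),
    )


def _check_design(x: np.ndarray) -> None:
    if x.size < 3:
        raise DegenerateSampleError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0.0:
        raise SingularDesignError("allele score has zero variance in the fitted sample")


def fit_outcome_on_score(pop: Population, selected_only: bool = True) -> FitResult:
    """OLS of outcome on allele score with intercept, classical standard errors.

    With ``selected_only`` the fit is restricted to participants (s == 1);
    otherwise the full intended population is used.
    """
    if selected_only:
        if pop.s is None:
            raise DegenerateSampleError("selection has not been applied")
        x, y = pop.g[pop.s], pop.o[pop.s]
    else:
        x, y = pop.g, pop.o
    _check_design(x)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    # Guard against negative round-off in a perfect fit.
    se = res.bse[1] if np.isfinite(res.bse[1]) else 0.0
    return _make_result(res.params[1], max(se, 0.0), x.size)


def ipw_fit(pop: Population, alpha: float, or_p: float, or_o: float) -> FitResult:
    """Weighted least squares of o on g among the selected, weights 1/Pr(S=1|P,O).

    Requires the true selection-model parameters; standard errors are
    heteroskedasticity-robust (HC0 sandwich), the usual choice for
    inverse-probability-weighted estimators.
    """
    if pop.s is None:
        raise DegenerateSampleError("selection has not been applied")
    sel = pop.s
    x, y = pop.g[sel], pop.o[sel]
    _check_design(x)
    prob = expit(alpha + math.log(or_p) * pop.p[sel] + math.log(or_o) * pop.o[sel])
    res = sm.WLS(y, sm.add_constant(x), weights=1.0 / prob).fit(cov_type="HC0")
    return _make_result(res.params[1], res.bse[1], x.size)


def ci_contains(fit: FitResult, value: float) -> bool:
    """True iff ``value`` lies in the 95% Wald interval (boundary counts)."""
    return fit.ci_low <= value <= fit.ci_high
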