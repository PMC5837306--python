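"""Replicate loops over scenario grids and table-style aggregation.

Each scenario runs ``n_reps`` independent replicates: a fresh intended
population of ``n_population`` individuals is simulated, the calibrated
logistic selection is applied, and the unadjusted outcome-on-allele-score
regression is fitted in the selected sample.  Replicate fits are aggregated
into the summary statistics printed in the null and non-null grid tables:
mean and SD of the coefficient and its z-score, and the number of 95%
intervals containing the reference value (zero for null scenarios, the true
coefficient gamma * r otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import calibrate_intercept
from .config import ScenarioConfig
from .errors import ColliderBiasError, ConfigurationError
from .estimation import FitResult, ci_contains, fit_outcome_on_score, ipw_fit
from .population import apply_selection, simulate_population

logger = logging.getLogger(__name__)

#: Recognised per-replicate estimators.
ESTIMATORS = ("ols", "ipw")


@dataclass(frozen=True)
class ScenarioSummary:
    """Across-replicate aggregation of one scenario."""

    config: ScenarioConfig
    mean_beta: float
    sd_beta: float
    mean_z: float
    sd_z: float
    true_beta: float
    n_ci_covering: int
    reference_value: float
    estimator: str = "ols"

    @property
    def variance_explained(self) -> float:
        """Phenotypic variance explained by the allele score, r^2, as a percentage."""
        return 100.0 * self.config.r**2


def run_scenario(cfg: ScenarioConfig, estimator: str = "ols") -> ScenarioSummary:
    """Run all replicates of one scenario and aggregate.

    The selection intercept is calibrated once per scenario (it depends on
    the odds ratios, gamma and the target fraction only).  Fully
    reproducible from ``cfg.seed``; replicate failures abort the scenario
    with the replicate index attached.
    """
    if estimator not in ESTIMATORS:
        raise ConfigurationError(f"unknown estimator {estimator!r}; expected one of {ESTIMATORS}")
    alpha = calibrate_intercept(cfg.or_p, cfg.or_o, cfg.gamma, cfg.target_fraction)
    reference = 0.0 if cfg.gamma == 0.0 else cfg.true_beta
    fits = []
    for rep in range(cfg.n_reps):
        try:
            fits.append(_run_replicate(cfg, rep, alpha, estimator))
        except ColliderBiasError as exc:
            raise type(exc)(f"replicate {rep}: {exc}") from exc
        logger.debug(
            "scenario or=(%.2f,%.2f) r=%.2f gamma=%.2f rep=%d n_selected=%d beta=%.5f se=%.5f",
            cfg.or_p, cfg.or_o, cfg.r, cfg.gamma, rep, fits[-1].n_used,
            fits[-1].beta, fits[-1].se,
        )
    return summarize(cfg, fits, reference, estimator)


def _run_replicate(cfg: ScenarioConfig, rep: int, alpha: float, estimator: str) -> FitResult:
    pop = simulate_population(cfg, rep)
    apply_selection(pop, alpha, cfg.or_p, cfg.or_o)
    if estimator == "ipw":
        return ipw_fit(pop, alpha, cfg.or_p, cfg.or_o)
    return fit_outcome_on_score(pop, selected_only=True)


def summarize(
    cfg: ScenarioConfig,
    fits: Sequence[FitResult],
    reference_value: float,
    estimator: str = "ols",
) -> ScenarioSummary:
    """Aggregate per-replicate fits into a ScenarioSummary."""
    betas = np.array([f.beta for f in fits])
    zs = np.array([f.z for f in fits])
    covering = sum(ci_contains(f, reference_value) for f in fits)
    ddof = 1 if len(fits) > 1 else 0
    return ScenarioSummary(
        config=cfg,
        mean_beta=float(betas.mean()),
        sd_beta=float(betas.std(ddof=ddof)),
        mean_z=float(zs.mean()),
        sd_z=float(zs.std(ddof=ddof)),
        true_beta=cfg.true_beta,
        n_ci_covering=int(covering),
        reference_value=reference_value,
        estimator=estimator,
    )


def run_grid(
    ors: Iterable[float],
    rs: Iterable[float],
    gamma: float,
    base_cfg: ScenarioConfig,
    estimator: str = "ols",
) -> list[ScenarioSummary]:
    """Cross odds ratios with allele-score correlations, in table order.

    Scenario order is descending OR then ascending r, matching the printed
    grids (3 ORs x 5 rs = 15 rows per table).  Equal odds ratios are applied
    to phenotype and outcome.
    """
    ors = sorted(set(float(v) for v in ors), reverse=True)
    rs = sorted(set(float(v) for v in rs))
    if not ors or not rs:
        raise ConfigurationError("ors and rs must be non-empty")
    out = []
    for or_ in ors:
        for r in rs:
            cfg = base_cfg.replace(r=r, gamma=gamma, or_p=or_, or_o=or_)
            logger.info("running scenario OR=%.2f r=%.2f gamma=%.2f", or_, r, gamma)
            out.append(run_scenario(cfg, estimator=estimator))
    return out


def summaries_to_frame(rows: Sequence[ScenarioSummary]) -> pd.DataFrame:
    """Tidy DataFrame with one row per scenario, raw (unformatted) values."""
    if not rows:
        raise ConfigurationError("no scenario summaries to tabulate")
    return pd.DataFrame(
        {
            "or": [s.config.or_p for s in rows],
            "r": [s.config.r for s in rows],
            "variance_explained": [s.variance_explained for s in rows],
            "mean_beta": [s.mean_beta for s in rows],
            "sd_beta": [s.sd_beta for s in rows],
            "mean_z": [s.mean_z for s in rows],
            "sd_z": [s.sd_z for s in rows],
            "true_beta": [s.true_beta for s in rows],
            "n_ci_covering": [s.n_ci_covering for s in rows],
            "n_reps": [s.config.n_reps for s in rows],
        }
    )


def write_summary_table(rows: Sequence[ScenarioSummary], destination: str | Path) -> None:
    """Write a headered TSV, one scenario per row, at table precision.

    Coefficients are printed to 4 decimals, z-scores to 2, variance
    explained as a percentage to 2.
    """
    frame = summaries_to_frame(rows).copy()
    for col in ("mean_beta", "sd_beta", "true_beta"):
        frame[col] = frame[col].map(lambda v: f"{v:.4f}")
    for col in ("mean_z", "sd_z", "variance_explained"):
        frame[col] = frame[col].map(lambda v: f"{v:.2f}")
    frame.to_csv(destination, sep="\t", index=False)
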