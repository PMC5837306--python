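"""Simulation of the intended study population and the selection mechanism.

Structural equations (all marginals unit-SD Normal):

    G ~ N(0, 1)                                 allele score
    P = r G + sqrt(1 - r^2) eps_P               phenotype, corr(G, P) = r
    O = gamma P + sqrt(1 - gamma^2) eps_O       outcome, Var(O) = 1

so the population-level regression coefficient of O on G is gamma * r.
Selection S is Bernoulli with log-odds alpha + ln(or_p) P + ln(or_o) O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from ._rng import replicate_rng
from .calibration import calibrate_intercept
from .config import ScenarioConfig, scenario_key
from .errors import ConfigurationError, DegenerateSampleError


@dataclass
class Population:
    """Per-individual simulated columns; ``s`` is None until selection is applied."""

    g: np.ndarray
    p: np.ndarray
    o: np.ndarray
    s: np.ndarray | None = None
    #: Continuation of the replicate's random stream (used for the selection draw).
    rng: np.random.Generator | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return self.g.size

    @property
    def n_selected(self) -> int:
        if self.s is None:
            raise DegenerateSampleError("selection has not been applied")
        return int(self.s.sum())

    def to_tsv(self, path: str | Path) -> None:
        """Dump the columns to a headered TSV (debugging aid; use reduced n)."""
        s = np.full(len(self), -1, dtype=int) if self.s is None else self.s.astype(int)
        with open(path, "w") as fh:
            fh.write("g\tp\to\ts\n")
            for gi, pi, oi, si in zip(self.g, self.p, self.o, s):
                fh.write(f"{gi:.6f}\t{pi:.6f}\t{oi:.6f}\t{si}\n")


def simulate_population(cfg: ScenarioConfig, replicate_index: int) -> Population:
    """Generate one replicate of the intended study population (selection unset).

    Deterministic given ``(cfg.seed, scenario, replicate_index)``: each
    replicate owns an independent PCG64 substream, which the returned
    Population carries forward for the subsequent selection draw.
    """
    if not 0 <= replicate_index < cfg.n_reps:
        raise ConfigurationError(
            f"replicate_index {replicate_index} outside [0, {cfg.n_reps})"
        )
    rng = replicate_rng(cfg.seed, scenario_key(cfg), replicate_index)
    n = cfg.n_population
    g = rng.standard_normal(n)
    p = cfg.r * g + math.sqrt(1.0 - cfg.r**2) * rng.standard_normal(n)
    o = cfg.gamma * p + math.sqrt(1.0 - cfg.gamma**2) * rng.standard_normal(n)
    return Population(g=g, p=p, o=o, rng=rng)


def apply_selection(
    pop: Population,
    alpha: float,
    or_p: float,
    or_o: float,
    rng: np.random.Generator | None = None,
) -> Population:
    """Fill ``pop.s`` with Bernoulli(expit(alpha + ln(or_p) p + ln(or_o) o)) draws.

    Uses the population's own stream continuation by default, so
    simulate -> select is reproducible from the replicate substream alone.
    Returns ``pop`` (mutated) for convenience.
    """
    if or_p <= 0.0 or or_o <= 0.0:
        raise ConfigurationError("odds ratios must be positive")
    rng = rng if rng is not None else pop.rng
    if rng is None:
        raise ConfigurationError("no random stream available for the selection draw")
    prob = expit(alpha + math.log(or_p) * pop.p + math.log(or_o) * pop.o)
    pop.s = rng.random(len(pop)) < prob
    return pop


def simulate_selected_population(cfg: ScenarioConfig, replicate_index: int) -> Population:
    """Convenience: simulate a replicate and apply its calibrated selection."""
    alpha = calibrate_intercept(cfg.or_p, cfg.or_o, cfg.gamma, cfg.target_fraction)
    pop = simulate_population(cfg, replicate_index)
    return apply_selection(pop, alpha, cfg.or_p, cfg.or_o)


def participation_mean_shift(pop: Population) -> tuple[float, float]:
    """(mean(p|s=1) - mean(p|s=0), mean(o|s=1) - mean(o|s=0)), in SD units."""
    if pop.s is None:
        raise DegenerateSampleError("selection has not been applied")
    sel = pop.s
    n1 = int(sel.sum())
    if n1 == 0 or n1 == len(pop):
        raise DegenerateSampleError("one selection class is empty")
    shift_p = float(pop.p[sel].mean() - pop.p[~sel].mean())
    shift_o = float(pop.o[sel].mean() - pop.o[~sel].mean())
    return shift_p, shift_o
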