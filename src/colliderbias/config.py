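"""Scenario configuration: the knobs of one selection-bias simulation scenario.

A scenario describes an intended study population of ``n_population``
individuals carrying three unit-variance Normal variables -- an allele score
G, a phenotype P (corr(G, P) = ``r``) and an outcome O (causal effect
``gamma`` of P on O) -- together with a logistic selection mechanism acting
on P and O with per-SD odds ratios ``or_p`` and ``or_o``, calibrated so that
a fraction ``target_fraction`` of the population is selected in expectation.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError

#: Default intended-population size.
DEFAULT_N_POPULATION = 9_000_000
#: Default marginal selection probability (~500k selected out of 9M).
DEFAULT_TARGET_FRACTION = 1.0 / 18.0

_INT_FIELDS = frozenset({"n_population", "n_reps", "seed"})


@dataclass(frozen=True)
class ScenarioConfig:
    """All parameters of a single simulation scenario.

    Parameters
    ----------
    n_population
        Size of the intended study population.
    r
        Target correlation between allele score and phenotype, in [0, 1).
    gamma
        Causal regression coefficient of phenotype on outcome (0 for null
        scenarios, 0.1 for the non-null grid).
    or_p, or_o
        Odds ratio of selection per 1 SD increase in phenotype / outcome.
    target_fraction
        Intended marginal selection probability.
    n_reps
        Number of Monte Carlo replicates.
    seed
        Master random seed; every replicate draws from an independent
        substream derived from ``(seed, scenario_key, replicate_index)``.
    """

    r: float
    gamma: float = 0.0
    or_p: float = 1.0
    or_o: float = 1.0
    n_population: int = DEFAULT_N_POPULATION
    target_fraction: float = DEFAULT_TARGET_FRACTION
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_population < 2:
            raise ConfigurationError("n_population must be >= 2")
        if not 0.0 <= self.r < 1.0:
            raise ConfigurationError(f"r must be in [0, 1), got {self.r}")
        if self.or_p <= 0 or self.or_o <= 0:
            raise ConfigurationError("selection odds ratios must be positive")
        if not 0.0 < self.target_fraction < 1.0:
            raise ConfigurationError("target_fraction must be in (0, 1)")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        # Outcome noise variance 1 - gamma^2 * Var(P) with Var(P) = 1.
        if 1.0 - self.gamma**2 < 0.0:
            raise ConfigurationError(
                f"gamma={self.gamma} leaves no room for unit-variance outcome noise"
            )

    @property
    def true_beta(self) -> float:
        """Population regression coefficient of outcome on allele score, gamma * r."""
        return self.gamma * self.r

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    # -- flat key=value serialization ------------------------------------

    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)!r}" for f in dataclasses.fields(self)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ScenarioConfig":
        """Parse a flat ``key = value`` config; '#' starts a comment."""
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"line {lineno}: expected 'key = value', got {raw!r}")
            key, _, value = (part.strip() for part in line.partition("="))
            if key not in known:
                raise ConfigurationError(f"line {lineno}: unknown key {key!r}")
            try:
                kwargs[key] = int(value) if key in _INT_FIELDS else float(value)
            except ValueError as exc:
                raise ConfigurationError(f"line {lineno}: bad value for {key}: {value!r}") from exc
        if "r" not in kwargs:
            raise ConfigurationError("config must set r")
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_text(Path(path).read_text())


def scenario_key(cfg: ScenarioConfig) -> int:
    """Stable 32-bit stream key identifying a scenario (seed excluded).

    Keyed on the scientific parameters only, so the same scenario re-run
    under a different master seed uses the same key, and any single
    replicate can be regenerated in isolation.
    """
    canon = "|".join(
        repr(getattr(cfg, name))
        for name in ("n_population", "r", "gamma", "or_p", "or_o", "target_fraction")
    )
    return zlib.crc32(canon.encode("ascii"))
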