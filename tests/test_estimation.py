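"""Regression fits: exact cases, closed-form oracle, invariances, IPW."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colliderbias import (
    DegenerateSampleError,
    FitResult,
    Population,
    ScenarioConfig,
    SingularDesignError,
    Z_CRIT,
    calibrate_intercept,
    ci_contains,
    fit_outcome_on_score,
    ipw_fit,
    simulate_population,
    simulate_selected_population,
)

from conftest import ols_slope_oracle


def _pop(g, o, p=None, s=None):
    g = np.asarray(g, dtype=float)
    o = np.asarray(o, dtype=float)
    p = g.copy() if p is None else np.asarray(p, dtype=float)
    return Population(g=g, p=p, o=o, s=None if s is None else np.asarray(s, dtype=bool))


def test_perfect_line_has_zero_standard_error():
    fit = fit_outcome_on_score(_pop([0, 1, 2], [1, 3, 5]), selected_only=False)
    assert fit.beta == pytest.approx(2.0, abs=1e-10)
    assert fit.se == pytest.approx(0.0, abs=1e-8)
    assert fit.n_used == 3


def test_fit_matches_closed_form_oracle():
    rng = np.random.default_rng(7)
    g = rng.standard_normal(500)
    o = 0.4 * g + rng.standard_normal(500)
    fit = fit_outcome_on_score(_pop(g, o), selected_only=False)
    beta, se = ols_slope_oracle(g, o)
    assert fit.beta == pytest.approx(beta, rel=1e-10)
    assert fit.se == pytest.approx(se, rel=1e-8)
    assert fit.z == pytest.approx(beta / se, rel=1e-8)
    assert fit.ci_low == pytest.approx(beta - Z_CRIT * se, rel=1e-8)


def test_fit_is_invariant_to_row_order():
    rng = np.random.default_rng(8)
    g = rng.standard_normal(300)
    o = rng.standard_normal(300)
    perm = rng.permutation(300)
    a = fit_outcome_on_score(_pop(g, o), selected_only=False)
    b = fit_outcome_on_score(_pop(g[perm], o[perm]), selected_only=False)
    assert a.beta == pytest.approx(b.beta, abs=1e-12)
    assert a.se == pytest.approx(b.se, abs=1e-12)


def test_selected_only_uses_the_selection_mask():
    g = np.array([0.0, 1.0, 2.0, 5.0, 6.0, 7.0])
    o = np.array([1.0, 3.0, 5.0, 0.0, 0.0, 0.0])
    s = np.array([1, 1, 1, 0, 0, 0])
    fit = fit_outcome_on_score(_pop(g, o, s=s), selected_only=True)
    assert fit.beta == pytest.approx(2.0, abs=1e-10)
    assert fit.n_used == 3


def test_degenerate_inputs_raise():
    with pytest.raises(DegenerateSampleError):
        fit_outcome_on_score(_pop([0, 1], [0, 1]), selected_only=False)
    with pytest.raises(SingularDesignError):
        fit_outcome_on_score(_pop([1, 1, 1], [0, 1, 2]), selected_only=False)
    with pytest.raises(DegenerateSampleError):
        fit_outcome_on_score(_pop([0, 1, 2], [0, 1, 2]), selected_only=True)  # s unset


def test_ci_contains_boundary_counts_as_containing():
    assert ci_contains(FitResult(0.0, 1.0, 0.0, -Z_CRIT, Z_CRIT, 10), 0.0)
    assert not ci_contains(FitResult(5.0, 0.1, 50.0, 5 - Z_CRIT * 0.1, 5 + Z_CRIT * 0.1, 10), 0.0)
    se = 0.01
    beta = Z_CRIT * se  # interval lower bound is exactly zero
    fit = FitResult(beta, se, beta / se, beta - Z_CRIT * se, beta + Z_CRIT * se, 10)
    assert ci_contains(fit, 0.0)
    just_above = math.nextafter(Z_CRIT * se, math.inf)
    fit2 = FitResult(just_above, se, just_above / se,
                     just_above - Z_CRIT * se, just_above + Z_CRIT * se, 10)
    assert not ci_contains(fit2, 0.0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(beta=st.floats(-10, 10), se=st.floats(1e-6, 10))
def test_fit_result_wald_interval_invariants(beta, se):
    fit = FitResult(beta, se, beta / se, beta - Z_CRIT * se, beta + Z_CRIT * se, 100)
    assert fit.ci_low < fit.ci_high
    assert fit.z * fit.se == pytest.approx(fit.beta, rel=1e-9, abs=1e-12)
    assert ci_contains(fit, beta)


def test_ipw_with_unit_odds_ratios_equals_unweighted_fit():
    cfg = ScenarioConfig(r=0.3, or_p=1.0, or_o=1.0, n_population=100_000,
                         n_reps=1, seed=3)
    pop = simulate_selected_population(cfg, 0)
    alpha = calibrate_intercept(1.0, 1.0, 0.0, cfg.target_fraction)
    plain = fit_outcome_on_score(pop, selected_only=True)
    weighted = ipw_fit(pop, alpha, 1.0, 1.0)
    assert weighted.beta == pytest.approx(plain.beta, abs=1e-10)


def test_ipw_removes_collider_bias_in_the_selected_sample():
    """True-weight reweighting recovers the (null) population coefficient."""
    cfg = ScenarioConfig(r=0.3, or_p=1.5, or_o=1.5, n_population=450_000,
                         n_reps=30, seed=19)
    alpha = calibrate_intercept(1.5, 1.5, 0.0, cfg.target_fraction)
    plain, weighted = [], []
    for rep in range(cfg.n_reps):
        pop = simulate_selected_population(cfg, rep)
        plain.append(fit_outcome_on_score(pop, selected_only=True).beta)
        weighted.append(ipw_fit(pop, alpha, 1.5, 1.5).beta)
    se_w = np.std(weighted, ddof=1) / math.sqrt(len(weighted))
    assert abs(np.mean(weighted)) < 3 * se_w          # unbiased within MC error
    assert abs(np.mean(weighted)) < abs(np.mean(plain))


def test_full_population_fit_recovers_the_true_coefficient():
    """Before selection, the slope of o on g is gamma * r (0.005 at r=0.05)."""
    cfg = ScenarioConfig(r=0.05, gamma=0.1, n_population=2_000_000, n_reps=1, seed=29)
    fit = fit_outcome_on_score(simulate_population(cfg, 0), selected_only=False)
    assert fit.beta == pytest.approx(0.005, abs=3.0 / math.sqrt(cfg.n_population))


def test_full_population_wald_intervals_have_nominal_coverage():
    """~95/100 unselected-fit CIs contain zero under the null."""
    cfg = ScenarioConfig(r=0.3, gamma=0.0, n_population=20_000, n_reps=100, seed=31)
    covered = sum(
        ci_contains(fit_outcome_on_score(simulate_population(cfg, rep),
                                         selected_only=False), 0.0)
        for rep in range(cfg.n_reps)
    )
    assert covered == pytest.approx(95, abs=3 * 2.2)


def test_fit_result_tsv_serialization(tmp_path):
    fit = FitResult(0.5, 0.1, 5.0, 0.304, 0.696, 42)
    path = tmp_path / "fit.tsv"
    fit.to_tsv(path)
    header, row = path.read_text().splitlines()
    assert header.split("\t") == ["beta", "se", "z", "ci_low", "ci_high", "n_used"]
    assert row.split("\t")[0] == "0.5" and row.split("\t")[-1] == "42"
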