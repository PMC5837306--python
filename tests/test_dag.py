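"""DAG library: preset behaviour, unit-variance policy, coin toy, stream identity."""

import math
from fractions import Fraction

import numpy as np
import pytest

from colliderbias import (
    ConfigurationError,
    DagSpec,
    ScenarioConfig,
    bias_report,
    build_preset,
    calibrate_intercept,
    enumerate_coin_toy,
    scenario_key,
    simulate_dag,
    simulate_population,
    apply_selection,
)


def test_coin_toy_enumeration_is_exact():
    """Two independent fair coins; conditioning on 'either is heads' induces -1/2."""
    result = enumerate_coin_toy()
    assert result["unconditional_correlation"] == 0.0
    assert result["conditional_correlation_exact"] == Fraction(-1, 2)
    assert result["conditional_correlation"] == -0.5
    assert result["conditional_correlation"] < 0  # spurious inverse association


def test_spec_validation_rejects_malformed_graphs():
    with pytest.raises(ConfigurationError):
        DagSpec(nodes=("G", "X"))  # unknown node
    with pytest.raises(ConfigurationError):
        DagSpec(nodes=("G", "G"))  # duplicate
    with pytest.raises(ConfigurationError):
        DagSpec(nodes=("G", "P"), edges=(("P", "G", 0.3),))  # backward edge / cycle
    with pytest.raises(ConfigurationError):
        DagSpec(nodes=("G", "P", "U"),
                edges=(("G", "P", 0.9), ("U", "P", 0.9)))  # > unit variance
    with pytest.raises(ConfigurationError):
        DagSpec(nodes=("G",), selection_parents=(("P", 1.5),))  # unknown sel parent
    with pytest.raises(ConfigurationError):
        DagSpec(nodes=("G",), selection_parents=(("G", -1.0),))
    with pytest.raises(ConfigurationError):
        build_preset("panelZ")


def test_implied_covariance_matches_hand_calculation():
    spec = build_preset("panelB", weight=0.5)
    cov = spec.implied_covariance()
    assert cov.loc["P", "G"] == pytest.approx(0.5)
    assert cov.loc["P", "U"] == pytest.approx(0.5)
    assert cov.loc["O", "U"] == pytest.approx(0.5)
    assert cov.loc["O", "G"] == pytest.approx(0.0)   # no open unconditional path
    assert cov.loc["O", "P"] == pytest.approx(0.25)  # via the shared factor U
    assert spec.noise_sd("P") == pytest.approx(math.sqrt(1 - 0.5))


@pytest.mark.parametrize("name", ["panelA", "panelB", "panelC", "panelD", "panelE", "panelF"])
def test_every_preset_node_has_unit_marginal_sd(name):
    data = simulate_dag(build_preset(name), n=120_000, seed=5)
    for node, values in data.items():
        if node == "s":
            continue
        assert values.std() == pytest.approx(1.0, abs=4.0 / math.sqrt(2 * 120_000))


def test_single_node_spec_is_standard_normal():
    data = simulate_dag(DagSpec(nodes=("G",)), n=150_000, seed=6)
    assert data["G"].mean() == pytest.approx(0.0, abs=4.0 / math.sqrt(150_000))
    assert data["G"].std() == pytest.approx(1.0, abs=4.0 / math.sqrt(2 * 150_000))


def test_selection_without_parents_is_pure_bernoulli():
    spec = DagSpec(nodes=("G", "O"), target_fraction=0.2)
    data = simulate_dag(spec, n=200_000, seed=8)
    s = data["s"]
    assert s.mean() == pytest.approx(0.2, abs=4 * math.sqrt(0.2 * 0.8 / 200_000))
    assert abs(np.corrcoef(s, data["G"])[0, 1]) < 4.0 / math.sqrt(200_000)


def test_core_preset_reproduces_the_main_simulator_stream_exactly():
    """Shared substream derivation: same seed -> identical draws, bit for bit."""
    cfg = ScenarioConfig(r=0.3, or_p=1.8, or_o=1.8, n_population=60_000,
                         n_reps=3, seed=21)
    pop = simulate_population(cfg, 1)
    alpha = calibrate_intercept(1.8, 1.8, 0.0, cfg.target_fraction)
    apply_selection(pop, alpha, 1.8, 1.8)
    spec = build_preset("core", r=0.3, gamma=0.0, core_or=1.8)
    data = simulate_dag(spec, 60_000, 21, replicate_index=1,
                        stream_key=scenario_key(cfg))
    assert np.array_equal(pop.g, data["G"])
    assert np.array_equal(pop.p, data["P"])
    assert np.array_equal(pop.o, data["O"])
    assert np.array_equal(pop.s, data["s"])


def test_spec_text_round_trip():
    spec = build_preset("panelE")
    again = DagSpec.from_text(spec.to_text())
    assert again.nodes == spec.nodes
    assert again.edges == spec.edges
    assert again.selection_parents == spec.selection_parents
    assert again.target_fraction == spec.target_fraction


def test_bias_report_requires_g_and_o():
    with pytest.raises(ConfigurationError):
        bias_report(DagSpec(nodes=("G", "P")), n=100, reps=2, seed=0)


def test_no_selection_effect_means_negligible_bias():
    spec = DagSpec(nodes=("G", "P", "O"), edges=(("G", "P", 0.3), ("P", "O", 0.3)),
                   selection_parents=(), target_fraction=0.3)
    report = bias_report(spec, n=100_000, reps=10, seed=4).set_index("association")
    assert (report["classification"] == "negligible").all()


#: caption claims per panel: (G-O classification set, P-O classification set)
PANEL_CLAIMS = {
    # induced G-O association despite no causal path
    "panelA": ({"negative", "positive"}, {"negative", "positive"}),
    "panelB": ({"negative", "positive"}, {"negligible"}),
    # causal G-O association distorted by selection
    "panelC": ({"negative", "positive"}, {"negative", "positive"}),
    "panelD": ({"negative", "positive"}, {"negligible"}),
    "panelE": ({"negative", "positive"}, {"negative", "positive"}),
    # SNP-driven selection: P-O biased, G-O untouched
    "panelF": ({"negligible"}, {"negative", "positive"}),
}


@pytest.mark.parametrize("name", sorted(PANEL_CLAIMS))
def test_panel_presets_exhibit_their_claimed_bias_behaviour(name):
    """Simulation-checked qualitative claims for each selection scenario."""
    report = bias_report(build_preset(name), n=1_000_000, reps=20, seed=9)
    report = report.set_index("association")
    go_claim, po_claim = PANEL_CLAIMS[name]
    assert report.loc["G-O", "classification"] in go_claim
    assert report.loc["P-O", "classification"] in po_claim


def test_core_preset_bias_matches_the_headline_grid_cell():
    """The core graph at study parameters shows the familiar negative G-O bias."""
    spec = build_preset("core", r=0.3, gamma=0.0, core_or=1.8)
    report = bias_report(spec, n=900_000, reps=20, seed=12).set_index("association")
    assert report.loc["G-O", "classification"] == "negative"
    assert report.loc["G-O", "bias"] == pytest.approx(-0.0079, abs=0.002)
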