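# Methods

## The problem

Large cohort and biobank studies are selected samples: participation (or
retention) depends on participants' characteristics. If two variables both
influence participation, then analysing only participants conditions on a
common effect of those variables — a collider — and induces an association
between them that does not exist in the intended study population. Because
genetic predictors of a phenotype are upstream of it, the induced
association propagates to allele scores: selection related to a phenotype
and an outcome biases the regression of the outcome on a polygenic score
for the phenotype, even when the score has no causal connection to the
outcome. This package quantifies that mechanism by direct Monte Carlo
simulation, supported by an exact large-sample (quadrature) computation of
the same quantities.

## Population model

One replicate simulates an intended study population of N individuals with
three unit-SD Normal variables:

    G ~ N(0, 1)                                   allele score
    P = r·G + sqrt(1 − r²)·ε_P                    phenotype
    O = γ·P + sqrt(1 − γ²)·ε_O                    outcome

with independent standard-Normal noise. This is the unique linear-Gaussian
construction with corr(G, P) = r and all marginal SDs equal to 1; the
population regression coefficient of O on G is exactly γ·r. The allele
score is continuous — the Gaussian limit of a many-variant polygenic score —
so there is no discrete-genotype, Hardy–Weinberg or LD structure. When
γ ≠ 0 the outcome noise is rescaled so SD(O) stays 1, which keeps the "per
SD" selection odds ratios comparable across scenarios and makes the true
coefficient γ·r (both grids' printed truths are consistent with this
choice).

## Selection model and calibration

Participation is a single Bernoulli draw per individual from a
log-odds-linear (logistic) model with no interaction:

    Pr(S = 1 | P, O) = expit(α + ln(OR_P)·P + ln(OR_O)·O)

The odds-ratio-per-SD parameterisation determines the logistic link; the
additive linear predictor honours the no-interaction assumption. The
intercept α is calibrated analytically, not by trimming: the linear
predictor is Gaussian with variance b_P² + b_O² + 2γ·b_P·b_O, so the
marginal selection probability is a one-dimensional logistic-normal
integral, evaluated with 201-node Gauss–Hermite quadrature and inverted for
α by Brent root-finding (absolute tolerance 1e−8 on the probability, which
the test suite verifies against an independent 10⁷-draw Monte Carlo
calibration to 1e−3 on α). The realized selected count is therefore
binomial around N × target fraction — "approximately 500 000 of 9 000 000"
rather than exactly — and α is re-calibrated for every (OR, γ) combination.

Under the study's settings, ORs of 1.2 / 1.5 / 1.8 per SD displace the
participant mean by 0.18 / 0.40 / 0.56 SD (0.2 / 0.4 / 0.6 to one decimal)
relative to non-participants.

## Estimation and aggregation

The analysis per replicate is the unadjusted OLS regression of outcome on
allele score among participants, with an intercept, classical standard
errors (the default in the period's software; at n ≈ 500 000 the
distinction from robust errors or t quantiles is immaterial) and 95% Wald
intervals using the Normal critical value 1.959964 (stated for
bit-reproducibility). Scenario summaries collect the across-replicate mean
and SD of the coefficient and its z-score, and count the replicates whose
interval contains the reference value — zero for null scenarios, γ·r
otherwise; boundary equality counts as containing.

The inverse-probability-weighted variant reweights participants by
1 / Pr(S = 1 | P, O) under the true selection model (WLS with HC0 sandwich
errors). With true weights the weighted selected-sample moments equal the
population moments identically, so the IPW estimand is exactly γ·r; the
tests verify the empirical removal of the induced bias directly where the
bias is large relative to Monte Carlo noise, and verify unbiasedness within
Monte Carlo error across the rest of the grid.

## Deterministic large-sample limits

`colliderbias.asymptotics` computes the infinite-population value of the
selected-sample slope without simulation. Conditional on (P, O), the score
is Gaussian with mean r·P (G is independent of O given P), so

    plim β_sel = r·Cov(P, O | S=1) / (1 − r²·(1 − Var(P | S=1)))

and the selected-sample moments of (P, O) are two-dimensional
logistic-normal integrals evaluated on a 96² Gauss–Hermite grid. The
collider bias is thus driven entirely by the covariance selection induces
between phenotype and outcome (zero before selection when γ = 0). This
provides a simulation-free cross-check used throughout the test suite, and
shows analytically that the bias does not depend on N — only z-scores and
coverage do, through the selected sample size.

## Reproducibility

One master seed governs a study. Each replicate draws from an independent
PCG64 stream seeded by (seed, scenario key, replicate index), where the
scenario key hashes the scientific parameters only; any replicate can be
regenerated in isolation, and re-running a scenario reproduces every
summary bit for bit. Each replicate regenerates the full population (no
reuse across replicates). The DAG simulator shares the same derivation, so
its `core` preset reproduces the main simulator's draws exactly.

## DAG scenario library

`colliderbias.dag` generalises the simulator to arbitrary linear-Gaussian
graphs over {G, P, O, U} with a logistic selection node: each node is a
weighted sum of its parents plus Normal noise rescaled to unit marginal SD,
and the selection intercept is calibrated through the same Gaussian
linear-predictor reduction. The figure-style captions constrain behaviour,
not structure, so the presets are the minimal graphs that exhibit each
claim, stated explicitly in `build_preset`'s documentation, and the tests
verify the behaviour by simulation rather than assuming the topology.
Preset defaults are edge weight 0.5, selection OR 2.5 per SD and a
half-selected sample — deliberately stronger than the main grids so that
each panel's qualitative classification (3-standard-error rule on the
paired selected-minus-full slope difference) is resolved with large margins
at n = 10⁶ and 20 replicates; all are exposed as parameters. The mortality
/ competing-risk style of example is represented as a selection node, not a
longitudinal survival process.

## Problem sizes

Full scale means N = 9 000 000, target fraction 1/18 and 100 replicates;
one scenario takes ~2.5 min on one CPU and the acceptance script (~5
full-scale scenarios plus one calibration population) ~15 min. The test
suite runs the z-score and coverage checks at full scale, because those
quantities scale with the selected sample size, and runs mechanism checks
(bias values, IPW removal, size invariance) at reduced populations of
450 000–900 000 with the 1/18 fraction held fixed, which leaves the bias
unchanged; replicate counts there are chosen so Monte Carlo error is small
against each tolerance. The two non-null grid cells in the acceptance
tests use 60 replicates with tolerances widened by the corresponding Monte
Carlo standard error.

## What the generator does and does not emulate

The generator reproduces the stated study conditions exactly: Gaussian
unit-SD variables, the r grid {0.05…0.30}, γ ∈ {0, 0.1}, equal per-SD
selection odds ratios {1.2, 1.5, 1.8} acting additively on the log-odds,
and expectation-calibrated baseline risk. It does not emulate discrete
genotypes, LD, measurement error, non-Gaussian phenotypes, interactions in
selection, time-varying attrition, or unknown selection mechanisms — so
passing tests certify the collider mechanism under the idealised design,
not the magnitude of bias in any particular real cohort. Real-cohort
analyses (birth-cohort retention, biobank participation) are out of scope:
they require external individual-level data.

## Known limitations and numerical notes

- The quadrature bias values agree with the published mean coefficients at
  printed precision across the whole grid, but the published mean z-scores
  are ~7–10% larger in magnitude than this model implies (e.g. −5.66
  implied vs −6.18 at OR 1.8, r = 0.30), a pattern consistent with an
  effective selected sample ~19% larger than 500 000. The generative
  details behind that gap are not recoverable from the described design;
  this package reports what the documented mechanism produces.
- Degenerate inputs raise typed errors (`DegenerateSampleError`,
  `SingularDesignError`, `ConfigurationError`, `NumericalError`) rather
  than propagating NaNs; a perfect fit reports se = 0 and an infinite z.
- Root-finding brackets for α are constructed from the linear predictor's
  6-SD range and cannot fail for valid inputs; quadrature node counts (201
  for calibration, 96² for moments) leave truncation error orders of
  magnitude below every tolerance used.
- Replicate failures abort a scenario rather than being skipped, so a
  summary always aggregates exactly `n_reps` fits.
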