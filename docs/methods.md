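# Methods

## Data model and effect-size conversion

The unit of analysis is a published study reporting a relative effect
estimate (hazard, odds or risk ratio) with a 95% confidence interval.
All measures are pooled on a common log scale without distinction: the
evidence bases this tool targets mix HR/OR/RR across studies, and a ratio
measure near the null is treated as exchangeable with the others. Each
record carries the attributes filters operate on: study population
(asian / caucasian / mixed / other), DNA source used for genotyping
(tumour / non_neoplastic / mixed / unknown), the set of assayed alleles,
and the outcome definition.

The published CI is inverted symmetrically on the log scale:
`y = ln rr`, `v = ((ln ci_upper − ln ci_lower)/(2z))²` with
`z = 1.959964` (the exact normal 97.5% point; 1.96 reproduces every
printed rounding equally). `y` is taken from the point estimate, not the
interval midpoint, so forest plots match published numbers even when a
published interval is asymmetric around its point estimate. A degenerate
(zero-width) interval is an error — no within-study variance is
representable. Published rounding can place a point estimate slightly
outside its own interval; the loader tolerates up to 1% relative excursion
before rejecting a row.

Filtering is conjunctive and declarative (`FilterSpec`): all set criteria
must hold; the RR ceiling is inclusive (`rr ≤ rr_max`, applied to point
estimates, matching the conventional "RR≤2" subset label); allele filters
test membership in the record's allele set, so a mixed-panel study
genotyping both *4 and *10 appears in both allele-defined subsets if its
population also matches — one defensible reading of subgroup labels that
couple population and allele. Exclusion lists are applied last. Filters
preserve order, are idempotent, commute, and append their description to
the evidence base's provenance string. De-duplication of overlapping study
samples is a curation-time concern requiring sample-linkage knowledge; the
loader enforces only unique study ids.

## Frequentist engine

Fixed-effect: inverse-variance weights `w_i = 1/v_i`,
`μ̂ = Σw_i y_i / Σw_i`, `var(μ̂) = 1/Σw_i`. Heterogeneity:
`Q = Σ w_i (y_i − μ̂_FE)²` (always computed with fixed-effect weights),
`I² = max(0, (Q − (k−1))/Q)` (0 when Q = 0), and the DerSimonian–Laird
moment estimator `τ² = max(0, (Q − (k−1))/(S₁ − S₂/S₁))`, truncated at
zero. Random-effects re-weights by `w*_i = 1/(v_i + τ²)`. Intervals use
normal quantiles on the log scale; the Knapp–Hartung small-sample
adjustment is deliberately omitted — the engine implements the plain
DerSimonian–Laird model. τ² requires k ≥ 2; pooling a single study is
allowed only in the fixed-effect model, where it is the identity.

## Bayesian engine

Model: `y_i | μ, τ ~ N(μ, v_i + τ²)`, `μ ~ N(m₀, s₀²)`, τ from a prior on
`[0, ∞)`. The μ prior is elicited from stated central-RR limits (see
README). The default τ prior is Jeffreys — the square root of the τ-block
Fisher information of the marginal model,
`p(τ) ∝ sqrt(Σ_i τ²/(v_i + τ²)²)` (the constant factor in the Fisher
information is irrelevant to an unnormalized density). The literature's
"Jeffreys prior for τ" admits more than one parameterization; this form,
standard in Bayesian meta-analysis, vanishes at τ = 0 and decays like
`sqrt(k)/τ`. Half-normal(scale) and Uniform(0, upper) priors are available
as alternatives, and a point-mass form (`Uniform` with upper → 0, or
`HeterogeneityPrior.fixed`) pins τ for conjugate checks.

Computation is deterministic grid marginalization, not MCMC: μ integrates
out in closed form (conjugate normal algebra), leaving a one-dimensional
unnormalized τ posterior `p(τ|y) ∝ p(τ)·p(y|τ)` evaluated on a uniform
grid of 2,001 points (configurable, ≥ 100) on `[0, τ_max]` and normalized
by trapezoid quadrature. The marginal posterior of μ is the corresponding
mixture of conditional normals `N(m_n(τ), s_n²(τ))`. The point estimate is
the posterior **median**, root-found on the mixture CDF to 1e-12; the
interval is the central (equal-tail) 95% credible interval; the posterior
mean is reported alongside, since published Bayesian summaries rarely say
which functional they print and median/mean can differ under skew.

**Grid truncation.** When `τ_max` is not given it is chosen adaptively: a
pilot scan (801 points) locates the τ posterior mode and spread, starts at
4×(mode + sd), then doubles until the outer half of the pilot grid holds
< 1e-5 of the mass — necessary because the Jeffreys posterior has
power-law tails at small k that a mode-based rule alone truncates
noticeably (the 2.5% μ quantile moves by ~1e-2 on 3-study instances
otherwise). A guard raises an error when more than 20% of τ mass sits in
the top tenth of a user-fixed grid, with the advice to enlarge `τ_max`;
for the improper Jeffreys prior with very few studies this doubles as a
numerical propriety check (k = 1 is accepted only if the grid posterior
verifiably concentrates).

Verification: the closed-form marginal likelihood is tested against 1-D
quadrature over μ (1e-8); full grid posteriors against an independent 2-D
quadrature oracle over (μ, τ) (quantiles to 1e-3); the τ-pinned path
against exact conjugate algebra (1e-8).

## Synthetic-data generator

`generate_evidence_base` draws exactly the model the engines assume:
`v_i` from a configurable law (default U(0.02, 0.2)), `θ_i ~ N(μ, τ²)`,
`y_i ~ N(θ_i, v_i)`, and emits records with `rr = exp(y_i)` and a 95% CI
rebuilt from the *true* `v_i` — so CI inversion is exact and the generator
is a fixture for every downstream layer. Default conditions: k = 50,
μ = 0.35 (RR ≈ 1.42, the scale of effects in this literature), τ = 0.2
(moderate heterogeneity), 500 replicates. Attributes are drawn from a
configurable mixture (default: 50% caucasian / 35% asian / 15% mixed;
DNA source 40% tumour / 50% non-neoplastic / 10% unknown) with allele
panels tracking the population's most-studied variant, so subgroup filters
are exercisable. Determinism: one root seed; replicate substreams via
`SeedSequence(seed, spawn_key=(replicate,))`.

What the generator does **not** emulate: publication bias and small-study
effects, non-normal study-level sampling error, correlated estimates from
overlapping samples, misreported or asymmetric CIs, and any systematic
link between attributes and effect size (except where segments are
explicitly configured, as in the bundled example). Passing recovery tests
therefore certify estimator correctness *under the assumed model*, not
robustness to those real-data pathologies.

The bundled 36-study CSV (`datasets/synthetic_cyp2d6_36studies.csv`,
regenerated bit-for-bit by `make_example_evidence_base()`) is a synthetic
stand-in for a real CYP2D6/tamoxifen evidence base: four segments with
true pooled RRs of 1.25 (Caucasian/*4), 2.44 (Asian/*10 — deliberately
above the plausibility ceiling of 2), 1.19 (tumour DNA, attenuated toward
the null, as loss-of-heterozygosity misclassification would produce) and
1.50 (mixed), so the qualitative subgroup and prior-shrinkage patterns of
that literature are reproducible on known ground truth. Users with the
real dataset can drop it, in the canonical CSV dialect, at
`data/shiny-2d6meta.csv`; the test suite then additionally checks the
all-studies conventional row against its published summary.

## Scenario reports

A scenario couples a filter with a list of analyses; the shipped
configuration (`datasets/default_scenarios.yaml`) runs six canonical
selection criteria (all studies; Caucasian/*4; Asian/*10; RR≤2; tumour
DNA; non-neoplastic DNA) plus two manually trimmed subsets (Asian/*10
restricted to RR≤2; RR≤2 restricted to *4-genotyping studies), each under
a conventional random-effects model and Bayesian models with vague
(RR 0.25–4) and informative (RR 1–2) priors. Scenarios reducing to k < 2
are flagged and skipped, not fatal; a run where every scenario is empty is
an error. Reports carry the SHA-256 of the canonical CSV serialization of
the input, the filter provenance and contributing study ids per cell, and
no timestamps — serialization is byte-stable. RR-scale numbers are printed
at 2 decimals in human-readable output and at full precision in JSON.

## Numerical and design choices

- Exact `z = 1.959964` throughout interval construction and elicitation.
- Mixture quantiles by Brent root-finding on `[min(m − 12s), max(m + 12s)]`.
- Jeffreys density grid point at τ = 0 has zero prior mass; zero-weight
  mixture components are dropped before quantile solving.
- Frequentist oracle in tests: exact rational arithmetic (`fractions`),
  which evaluates the defining formulas with zero rounding error because
  binary floats are exact rationals.
- statsmodels' DL implementation returns the untruncated moment estimate;
  cross-checks compare against its value truncated at zero, which is the
  estimator implemented here.
- Simulation problem sizes in the test suite (500 replicates at k = 50 for
  recovery; 1,000 instances for the rational-arithmetic oracle; k ≤ 10 for
  the quadrature oracle) were chosen to make sampling error small relative
  to the asserted tolerances while keeping the default suite fast on a
  laptop.

## Known limitations

- No REML / Paule–Mandel τ² estimators, meta-regression, funnel-plot or
  publication-bias statistics.
- No Knapp–Hartung adjustment; frequentist intervals can undercover for
  small k with heterogeneity.
- The Bayesian model places no prior on study-level effects beyond the
  exchangeable normal; no model averaging over τ priors.
- Literature retrieval, screening, and risk-of-bias scoring are out of
  scope: the evidence-base CSV is the interface.
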