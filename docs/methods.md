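# Methods

## Outcome and variable coding

The outcome is a single 5-point Likert rating of overall drill
effectiveness.  It is dichotomized at a fixed threshold (default 3.16, the
survey sample mean): scores **at or below** the threshold are *low*
effectiveness (coded 1, the modelled event), scores above it *high*
(coded 0).  With integer scores this sends 1–3 to low and 4–5 to high.  The
threshold is a codebook parameter rather than a quantity recomputed from
data, so the published split is reproducible on any input; it must lie in
[1, 5].

Skill self-ratings arrive as raw 1–5 scores and are collapsed to
*bad* (1–3) / *good* (4–5).  Every other variable is declared in the
codebook with an ordered level list, an **adverse level** (coded 1 in the
regression; the exposure expected to worsen ratings) and a reference level.
Orientation is always declared, never inferred from data: the published
cross-tabulation percentages and the published odds-ratio directions are not
mutually consistent for some variables (the columns may be transposed at the
source), and the χ² statistic is invariant to that, so the package asserts
no directional claims about the published tables.

Records with any missing declared variable are excluded whole, with the
count logged and carried on the coded dataset (`on_missing="drop"`,
mirroring the survey's own exclusion of incomplete questionnaires);
`on_missing="raise"` instead fails on the first incomplete record, naming
the missing variables.

## Chi-square screening

Each variable's r×2 table against the high/low split is tested with the
uncorrected Pearson statistic Σ(O−E)²/E, df = r−1.  No continuity
correction is applied — the published statistics reproduce only without it
(Yates-corrected values do not).  No multiple-testing adjustment is applied,
matching the screen-then-regress design.  Expected counts below 5 are
logged but never switch the test to an exact variant.  Degenerate tables
(an empty level margin after dropping unobserved levels, or a constant
predictor) are reported per-variable with the reason and excluded from
selection without aborting the remaining tests.  Reported statistics are
rounded half-up to one decimal, the display convention of the source
tables.

## Logistic model

All screened binary-coded variables enter one joint fit of the
low-effectiveness indicator; there is no stepwise selection.  Multi-level
demographics (age group, work tenure) cannot enter the indicator design
and are recorded as excluded if they pass the screen.  The fit is
Newton–Raphson on the Bernoulli log-likelihood (equivalently IRLS):

- start at the zero vector with the intercept at the empirical logit;
- step-halving whenever a full Newton step would decrease the
  log-likelihood, so the likelihood is non-decreasing across iterations;
- convergence when the largest absolute score entry **or** the largest
  absolute coefficient change drops below 1e-8, within 50 iterations.
  Either condition suffices: a vanishing score is the optimum, while a
  vanishing accepted step means the likelihood can no longer improve at
  floating-point resolution (at n in the tens of thousands the
  log-likelihood's absolute rounding floor is reached while the score floor
  is still ~1e-5 absolute, ~1e-9 relative);
- covariance = inverse observed information at the optimum; standard errors
  are the square roots of its diagonal.

Rank-deficient designs raise a collinearity error naming the dependent
columns; diverging coefficients (|β| > 30) or a singular information matrix
mid-iteration raise a separation error.  Wald statistics are (β/SE)²
referred to χ²(1); 95% intervals use z = 1.959964.  Odds ratios are
reported with the event being a *low* rating and predictors being adverse
indicators, so OR > 1 reads "raises the risk of a low rating".

The goodness-of-fit check is a Hosmer–Lemeshow statistic over quantile
groups of fitted probability (default 10).  Ties stay within one group, so
bins may collapse; df = (distinct groups) − 2, and a collapse below 3
groups makes the test undefined (reported as a skip by the pipeline, not a
crash).  The published analysis reports a single goodness-of-fit p-value
from an unstated grouped method; that printed value depends on the
unavailable raw data and is not asserted anywhere.

A note on the power of this check: omitting an *independent* covariate is
nearly undetectable by decile calibration — the refitted main-effects
logistic re-calibrates almost perfectly (measured p-values 0.59–0.99 across
replicates at n = 50,000) because omitted-variable bias attenuates
coefficients without bending the calibration curve.  The test suite
therefore probes power with a genuinely miscalibrated truth (a strong
omitted interaction), which is rejected essentially always at that n.

## Synthetic surveys

The generator emulates the published study conditions and is the test bed
for every downstream stage:

- **n = 1,859** respondents by default;
- every explanatory variable drawn independently at its published pooled
  prevalence (high + low counts over 1,859);
- the seven published adjusted odds ratios, as ln(OR) on the adverse level,
  are the complete generating model (nonzero effects only for those seven;
  the remaining fourteen variables are null covariates);
- the intercept is found by Brent root-finding (to 1e-10) so the
  population-averaged low rate equals 990/1859 ≈ 0.5325.  Because
  covariates are independent, the marginal rate is an exact finite mixture
  over the 2⁷ effect-covariate combinations — no Monte Carlo in the
  calibration itself;
- the latent binary outcome is rendered as a Likert score — low → uniform
  on {1, 2, 3}, high → uniform on {4, 5} — so dichotomizing at 3.16
  recovers it exactly (zero-discrepancy round trip); likert-coded skill
  covariates are rendered the same way from their bad/good draw;
- one `numpy.random.default_rng(seed)` stream drives everything; identical
  configs give byte-identical datasets.

What the generator does **not** emulate: covariate correlation (the source
reports no joint distribution; independence is the simplest structure
consistent with the marginals), the multistage cluster sampling design
(also unmodelled in the source analysis), any non-uniform score
distribution within the low/high bands, and item-level missingness.
Passing tests therefore demonstrate correctness of the estimators under
the declared generating model, not robustness to design effects or
confounding structure in the real survey.

## ISM engine

- **Closure**: M = (R + I)^λ under Boolean arithmetic, computed by repeated
  Boolean squaring until stable (λ ≤ k−1; the contract is the result, not
  the algorithm).  Validation accepts 0/1 square matrices only, naming the
  first offending entry otherwise; diagonal 1s are coerced to 0 with a log,
  since reflexivity is supplied by the identity.
- **Sets**: R(Sᵢ) is row i of M, A(Sᵢ) column i, T(Sᵢ) their intersection.
- **Levels**: iteratively extract all factors of the current submatrix with
  R(Sᵢ) ∩ A(Sᵢ) = R(Sᵢ), record them as the next level, delete their rows
  and columns.  Level 1 (first extracted) is the *surface*; the deepest
  level is the *bottom* (root drivers).  A round that extracts nothing is
  impossible for a true reachability matrix and raises an
  internal-consistency error (guards corrupt input such as an unclosed
  cycle).  The extraction condition is the standard reachable-within-
  antecedent criterion; for every strictly reaching pair the influencer
  lands strictly deeper, and mutually reachable factors always share a
  level.
- **Hierarchy digraph**: cross-level edges are the direct adjacency links
  between distinct strongly connected groups that survive transitive
  reduction of the condensation (a link implied through an intermediate
  retained group is dropped); within-level edges are the adjacency links
  inside one mutually reachable group, kept as drawn.  The published figure
  does not print its exact edge set, so transitive reduction is a rendering
  convention of this package, not a source-verified result.  Export is
  plain DOT text with one `rank=same` subgraph per level and deterministic
  ordering.

The expert adjacency over the seven significant factors ships in
`logistic_ism.datasets` (parsed from the published row-major digit string;
its closure reproduces every published reachable/common set).  The
published *reachability* matrix print disagrees with the published set
table in at least one digit, so the set table is treated as authoritative
and the printed closure string is not asserted.

## Pipeline

`run_pipeline` chains code → screen → fit → ISM → report.  ISM runs only on
factors whose mapped predictors are significant in the joint model: the
label↔variable mapping is declared in config (defaulting to the published
S1…S7 labelling), non-selected factors are excluded by restricting the
adjacency to the selected sub-matrix, and every exclusion or skipped stage
is recorded with a reason in the report.  Reports carry a provenance block
(config hash, seed, package version) and serialize deterministically —
reruns with the same config are byte-identical.

## Problem sizes used in tests

Simulation-based checks scale their n to what the property needs:
estimator recovery uses n = 200,000 (each coefficient within 3 SEs of
truth) and the 2,000/20,000/200,000 ladder for error monotonicity (20
seeds); Wald interval coverage uses 1,000 replicates at n = 5,000, holding
the Monte-Carlo error of the coverage estimate near 0.7 points against the
93–97% band; Hosmer–Lemeshow calibration and power use 100 and 20
replicates at n = 50,000; the χ² type-I error uses 1,000 tables at
n = 2,000 against a [0.035, 0.065] band.  The end-to-end hierarchy-recovery
test runs at n = 20,000, where all seven generating effects are detected
with probability ≈ 1; at the survey's own n = 1,859 the weakest effects
(OR ≈ 1.3–1.4) have only ~75–80% power, so which factors reach
significance there varies by seed — the survey-sized test asserts
completion and internal consistency, not a fixed selected set.

## Known limitations

- Adjusted odds ratios from the original survey are not reproducible
  without the raw respondent data; the package substitutes parameter
  recovery on simulated data with the published estimates as truth.
- The abstract's 95% CI for the prevalence (50.6–55.4) does not match a
  standard Wald interval for 990/1859 and its method is unstated; the
  package reports the rate only.
- The expert elicitation behind the adjacency matrix is out of scope; the
  matrix is a given input, and no MICMAC driving/dependence analysis is
  performed.
- No survey weights or cluster-robust variances; no imputation.
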