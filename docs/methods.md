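# Methods

## The estimand and the selection model

The analysis model is a logistic regression of a binary outcome Y on a
K-level categorical exposure X (dummy-coded against category 0) and
confounders C:

    logit P(Y = 1 | X, C) = β₀ + βX·X + βC·C.

Complete-records analysis (CRA) fits this model to the subset with R = 1,
where R indicates that Y, X and every confounder are observed. All bias
statements in the package are *asymptotic*: they concern the probability
limit of the CRA estimator, defined as the root of the population weighted
score

    Σ_{x,c,y} π(x,c) · P(y|x,c) · P(R=1|x,y,c) · (y − expit(z(x,c)'β)) · z(x,c) = 0,

where z(x,c) is the fitted design vector. Because the weighted log-likelihood
is strictly concave, this root is unique, and the oracle solves it by Newton
iteration to a score residual below 1e-10; a parameter is called
asymptotically unbiased when its limiting value differs from the generating
one by less than 1e-8 (solver precision, orders of magnitude below any
epidemiologically meaningful effect).

A useful way to see every verdict at once: conditional on selection,

    logit P(Y=1 | X, C, R=1) = β₀ + βX·X + βC·C + g(X, C),
    g(X, C) = log [ P(R=1|X,1,C) / P(R=1|X,0,C) ].

Covariate-only mechanisms have g ≡ 0 (no bias anywhere). Outcome-only
mechanisms give a constant g = log t(1)/t(0), absorbed by the intercept (the
case-control result). Mechanisms factorizing as s(X,C)·t(Y,C) give
g = g(C), absorbed by the intercept and the confounder terms *provided the
fitted model is flexible enough in C to absorb it* — exactly true when C is
dummy-coded, and true for the benchmark catalog because its age-dependent
selection indices are linear in age, which the fitted age term absorbs. Joint
non-factorizable X,Y-dependence leaves an X-dependent offset that contaminates
βX. The factorization test is therefore equivalent to "g does not vary with
X", which for a positive selection matrix M[x,y] per confounder value is the
vanishing of every 2×2 log cross-ratio; the package tests exactly that, with
tolerance 1e-8 on |log cross-ratio| (grids are exact analytic evaluations,
not estimates). Whole zero rows/columns are excluded from the test; isolated
zeros make the cross-ratio undefined and are reported non-factorizable with a
warning.

Mechanisms are represented as products of (i) linear-index terms
expit(a + Σ_v b_v (v − center_v)/scale_v) and (ii) branch terms keyed on the
outcome value. Branching on Y only is sufficient for the benchmark catalog
and for every mechanism class in the taxonomy; general branching variables
are deliberately out of scope. Dependence sets are probed numerically on a
deterministic grid (categorical variables exhaustively, continuous
confounders on a 9-point equal-probability quantile grid — a heuristic that
is exact for indices monotone in the confounder).

## The logistic fitter

Maximum likelihood by Newton iteration on the score with step-halving (a step
is halved until the log-likelihood does not decrease), convergence at
max |score component| < 1e-8, at most 50 iterations. Standard errors are
model-based Wald (inverse observed information); separation is declared when
a coefficient passes 15 in absolute value during iteration. Because the raw
intercept extrapolates to age 0 — far outside the data and legitimately of
magnitude 15+ — the fitter internally centers all non-intercept columns at
their (weighted) means and maps the solution back; the divergence bound is
thus judged against the log-odds at the covariate mean, and conditioning
improves substantially. Replicates whose fit fails (non-convergence or
separation, in practice a covariate cell with zero events) are excluded from
Monte Carlo means and reported as a failure count; above 10% failures the
summary carries a prominent warning.

Age enters the model as a hinge basis (age, (age−30)⁺, (age−40)⁺, (age−50)⁺,
(age−60)⁺): continuous, piecewise-linear, interpretable slope changes at the
knots. BMI is categorized with left-closed bins at cutpoints 20/25/30.
Effect modification is a per-exposure-category slope on (age − 37.32) in
log-odds per year; fitting the main-effects model to data generated with a
non-zero interaction is the package's controlled form of model
misspecification.

## The synthetic cohort

The generator emulates the structure of an occupational flight-crew cohort
whose raw data are not publicly deposited. Calibrated features (these are the
study conditions, not tuning knobs):

- n = 15,683; outcome prevalence 354/16,327 ≈ 0.0217, hit by root-finding
  the intercept against a fixed-seed covariate sample of 200,000 (residual
  < 1e-6);
- age: truncated normal on [18, 65] whose *truncated* mean and SD equal
  37.32 and 10.79 (the underlying normal parameters are solved for, since
  truncation would otherwise shift the moments the benchmark mechanisms
  standardize by);
- exposure: three flying-hours tertiles, marginally uniform, generated by an
  ordered-logit rule in standardized age whose slope and thresholds are
  solved by quadrature so that corr(age, X) ≈ 0.5 — accrued flying hours
  rise with age;
- exposure log odds ratios 0.64 and 0.70 (middle and top tertile vs lowest)
  at the mean age; with interaction strength γ > 0 they decline by γ per SD
  of age, and the misspecified variant used in tests sets γ = 0.25.

The joint distribution of the remaining confounders was never published;
the defaults — 94% male, smoking (never/former/current) = (0.55, 0.30, 0.15),
BMI ~ N(25.0, 3.5²), route type (0.10, 0.25, 0.40, 0.25), all independent of
age — are plausible for professional flight crew and fully configurable. They
were chosen, in part, so that rare cell × event combinations (female deaths,
obese deaths) retain non-trivial expected counts under 25–50% selection at
2% prevalence; nothing in the calibrated quantities depends on them beyond
the configured targets. Confounder effects on mortality (age slope 0.06/yr
with mild steepening at the knots, male +0.5, former/current smoking
+0.3/+0.8, U-shaped BMI, small route effects) are likewise plausible-scale
choices, not estimates of any real cohort.

What the generator deliberately does *not* emulate: censoring and follow-up
time (the outcome is a bare 15-year death indicator), record linkage,
covariate measurement error, and any real correlation among sex, smoking,
BMI and route. Passing tests therefore demonstrate the missingness theory on
a faithful structural stand-in, not a re-analysis of the original study.

## Discretization for the oracle

The oracle needs a finite joint distribution. Age is placed on an equal-mass
quantile grid *stratified by the hinge-knot intervals* (at least two nodes
per interval) so every basis column has support and the design stays full
rank; 17 nodes by default, and refining 9 → 33 moves the limit by < 1e-3 in
the tests. BMI keeps only its category (any representative value inside a
bin is exact for a categorical basis); sex, smoking, route and the
exposure-given-age rule are exact. Crucially the outcome probabilities are
evaluated *at the grid points with the same basis the fit uses*, so
discretization introduces no misspecification: under any covariate-dependent
mechanism the oracle reproduces the generating coefficients to machine
precision, which the tests assert.

## Simulation designs and their statistics

Two designs are provided, and the distinction matters:

- `fixed_cohort` (default, mirroring the benchmark study): one cohort,
  percent bias measured against its own full-data fit. For a single finite
  cohort the expected CRA estimate under a covariate- or outcome-dependent
  mechanism differs from the full-data estimate by a cohort-specific
  O(n^(-1/2)) offset — the weighted and unweighted fits of the *same*
  empirical data are distinct functionals. Percent "biases" of a few percent
  under asymptotically unbiased mechanisms are therefore expected in this
  design and shrink only with cohort size, not with replications.
- `redraw_each_rep` with `reference_mode="true_value"`: a fresh cohort per
  replicate, bias against the generating value. This is the statistically
  calibrated design — the Monte Carlo standard error of the mean is an
  honest yardstick — and is what the acceptance tests use (500 replicates;
  at that size 4 MC SEs correspond to roughly ±8% on the smaller log odds
  ratio, comfortably above the ~1% small-sample bias of rare-event logistic
  estimates and far below the >+150% effect of the non-factorizable
  mechanism).

Replicate seeding is deterministic: replicate r of mechanism i draws from
`default_rng([base_seed + r, i + 1])` (the non-zero second word matters:
NumPy's SeedSequence ignores trailing zero entropy words, which would
otherwise collide with the cohort-generation stream), and in redraw mode the
cohort of replicate r comes from `default_rng([base_seed + r, 1000003])` so
all mechanisms see identical cohorts.

## Missingness diagnostics

For each partially observed variable the package fits a logistic model of
the indicator "variable observed" on the remaining analysis variables, using
the same bases as the outcome model, with the outcome itself as a predictor.
Association is judged per variable *group* (dummy sets, the age basis) by a
joint Wald test at α = 0.05 **and** a minimum standardized magnitude of 0.1,
where magnitude is the SD of the group's contribution to the linear
predictor — one scale for continuous and categorical variables alike. Both
thresholds are configurable; the method's own guidance is that significance
alone is the wrong criterion, so significant-but-tiny effects are reported
separately as negligible, and large-but-insignificant ones are flagged
("large but imprecise") rather than silently dropped. Note that the
SD-of-contribution scale deflates effects of rare binary predictors (a rare
outcome with a log-odds effect of 1 has magnitude ≈ 0.15); with very rare
outcomes the `min_effect` floor should be lowered accordingly.

The detected association classes map to a verdict table keyed by the role of
the missing variable; the single bias-causing pattern is joint association
with both X and Y. Dependence on the missing variable *itself* is
unobservable and harmless on its own; it enters the reports through the
plausible-mechanism lists, and callers can declare it contextually by adding
the variable's own class to the association set. Every favorable verdict
carries a cancellation caveat (a bias-causing mechanism can masquerade as an
innocuous pattern), and multi-variable missingness is handled by diagnosing
each variable among records complete on the others — explicitly labeled an
approximation in the reports. Variables with less than 0.5% missingness are
skipped as negligible (documented in the report), mirroring how trace
missingness is treated in practice.

## Problem sizes used by the tests

Parameter recovery runs at n = 10⁵; summary-statistic calibration at
n = 10⁶; oracle/Monte-Carlo agreement at a single n = 10⁶ draw per
mechanism; the factorization equivalence on 200 randomized discrete
scenarios; the Monte Carlo pattern checks at 500 fresh-cohort replicates;
diagnostic calibration at 40 cohorts of n = 8,000 per scenario with a ≥90%
agreement bar for standardized missingness effects ≥ 0.3. These sizes keep
the full suite under a few minutes while leaving all statistical margins at
4 Monte Carlo SEs.

## Known limitations

- The asymptotic guarantees assume a correctly specified outcome model; the
  package quantifies (oracle) and illustrates (simulator) interaction-type
  misspecification but offers no correction for it.
- The factorization test is exact only on the probe grid; for mechanisms
  non-monotone in a continuous confounder between grid points it is a
  heuristic.
- Diagnostics are necessarily one-sided: they can make bias *plausible* or
  *implausible*, never certain — cancellation and self-dependence are
  invisible in the observed data.
- No survival/censoring handling, no multiple imputation, no inverse
  probability weighting: the toolkit studies CRA itself, not its
  alternatives.
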