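# Methods

## Model and likelihood

`twinvc` fits multi-group normal-theory models to same-sex twin pairs.
Writing y = (y1, y2) for the two members of a pair, the ACE model assumes

* E[y1] = E[y2] = mu (one grand mean in the 2-group model; per-sex means
  mu_M, mu_F in both 4-group variants),
* Var(y1) = Var(y2) = T = A + C + E,
* Cov(y1, y2) = A + C for MZ pairs and A/2 + C for DZ pairs.

A is additive genetic variance (MZ twins share all of it, DZ twins half on
average), C shared-environment variance (shared fully by both zygosities),
E unique-environment variance including measurement error. Dominance
variance D (MZ sharing 1.0, DZ 0.25) is confounded with C in this design
and is therefore not estimated simultaneously; instead the fitted ACE
shares can be reparameterized exactly into ADE shares (`reparam` module).

**Unbounded estimation.** The likelihood is parameterized directly in
(A, C, E), with no non-negativity bounds on A and C. Rationale: squared
path coefficients impose an implicit zero lower bound, which truncates the
sampling distribution of the estimates; under a true null the bounded
estimator has strictly positive mean, while the direct estimator averages
to zero (verified by simulation in the acceptance suite), and 1-df
likelihood-ratio statistics keep the regular central chi-square reference
rather than a boundary mixture. Positive definiteness of each group's
expected covariance matrix (and E > 0, implicitly T > 0) is enforced by
returning +inf from the objective, not by hard bounds, so the feasible
region's boundary is never an attractor.

**FIML.** A pair with one member observed contributes the marginal
univariate normal log-density; both-missing pairs are dropped and counted.
The likelihood is evaluated from per-group sufficient statistics (sums,
squares and cross-products of complete pairs, plus per-twin-order sums for
half-pairs), which is algebraically identical to summing the per-pair
log-densities (`pair_loglik`; a test asserts the identity to 1e-9) and is
what makes the simulation studies below affordable — a 4-parameter ML fit
costs well under 50 ms.

**Models and parameter counts.** sat2 (10 = 2 groups x [2 means, 2
variances, covariance]), ace2 (4), sat4 (20), ace4_free (8), ace4_equal
(5: two means + shared A, C, E). The saturated models and ace4_free
factorize over independent groups and are fitted group-wise (never more
than 5 joint parameters). ace2-vs-sat2 (6 df) tests the equal
means/variances assumptions across twin order and zygosity;
ace4_equal-vs-ace4_free (3 df) tests sex heterogeneity of the variance
components. Means are per-sex in *both* 4-group variants, so the
heterogeneity test isolates the components; this is configurable in
principle but fixed here because the phenotypes entering the models are
already sex-residualized.

## Optimization

Starting values come from the moment estimators A0 = 2(covMZ − covDZ),
C0 = 2 covDZ − covMZ, E0 = var − covMZ (clipped to at least 5% of the
variance); submodels with a pinned component (CE, AE) use starts that
match the pooled covariances under the constrained expectation. The
minimizer is Nelder–Mead (xatol 1e-9, fatol 1e-11) followed by a restart
from the solution, with up to three jittered restarts on failure; a
derivative-free method was chosen because the +inf barrier at the
positive-definite boundary breaks quasi-Newton line searches, and with
moment starts the simplex converges to the oracle tolerances used in the
tests (saturated ML equals sample moments to 1e-6; −2lnL self-consistency
to 1e-8). Infeasible starts are blended toward the diagonal-dominant safe
point (A = C = 0, E = var). Convergence is reported, never silently
assumed; the finite-difference gradient norm at the solution is stored on
the `FitResult`.

## Profile-likelihood confidence intervals

CIs are computed for the standardized shares (a², c², e²), matching how
results are reported. The share of interest is constrained, the mean(s),
total variance T and one other share are re-optimized, and a bound is the
constrained value at which the profile −2lnL exceeds the minimum by the
chi-square(1) quantile (3.841 at 95%). Bounds are located by expanding
brackets from the point estimate followed by bisection to 1e-5; a test
checks both bounds against a dense grid search of the profile to 1e-3.
If a bound cannot be bracketed before the positive-definite region ends,
a one-sided interval is returned with a diagnostic on the fit object.
Coverage at 500 pairs/zygosity is validated by simulation (profile-excess
containment test, exactly equivalent to CI containment and much cheaper
than locating both bounds per replicate).

## Preprocessing

Fixed effects of sex, age (months), race/ethnicity (four dummies: Black,
Hispanic, Asian, Other vs the White reference) and site (three dummies vs
the UMN reference) are removed by ordinary least squares with both twins
stacked as individual rows; within-pair dependence is deliberately ignored
at this stage (it only costs efficiency for the fixed-effect estimates)
and handled downstream in the likelihood. Residuals are standardized once
— mean and SD (n−1 divisor) computed before any masking — and values with
|z| strictly greater than 4 are set to missing, with no re-standardization
afterwards. The order matters and is fixed: standardize, then mask once.
Design columns that are constant in the given sample (e.g. an unpopulated
race category) are dropped to keep the design full rank; genuinely
collinear columns raise an error naming them.

## Descriptives

Pearson product-moment correlations between twin 1 and twin 2 are computed
over complete pairs, overall by zygosity and stratified by sex, using the
recorded twin order (a double-entry intraclass option exists, off by
default). Variance homogeneity across zygosity (and zygosity x sex) uses
the classic mean-centered Levene test on individual-level values; the test
treats individuals as independent, which twin data are not — p-values are
reported descriptively, consistent with their screening role.

## Synthetic cohorts

The generator emulates a four-site, population-ascertained US cohort of
9–10-year-old same-sex twin pairs: pair-level sex (default 56.5% female),
age uniform over 108–131 months shared within pair, site roughly balanced
over four levels and race margins of about 66/14/10/0.2/10 percent —
margins only, with no cross-tabulated covariate structure. Phenotypes are
bivariate normal around a linear predictor with configurable coefficients
(defaults are modest, realistic effects: 0.2 SD for sex, 0.01 per month of
age, ≤ 0.1 SD for site/race contrasts); the residual pair covariance
follows the A/C/D/E spec exactly (MZ sharing 1.0/1.0/1.0, DZ 0.5/1.0/0.25).
Missingness and outlier contamination (displacement to ± m SD of the
observed distribution) are injected value-wise, flagged, and driven by a
separately derived seed so each stage reproduces independently. What the
generator does **not** emulate — non-normal traits, floor/ceiling effects,
opposite-sex pairs, rater/contrast effects, G×E or assortative mating — is
exactly what passing tests cannot certify about real data: the test suite
establishes correctness of the estimators under the model's own
assumptions, not robustness to their violation.

## Power analysis

Power for detecting A (or C) is estimated by simulation: each replicate
draws standardized cohorts with the implied rMZ/rDZ, fits the full ACE and
the reduced (CE or AE) model, and performs the 1-df LRT against the
central chi-square critical value (a 50:50 boundary-mixture reference is
available for comparison only). Replicate fit failures are excluded; more
than 2% aborts. The analytic cross-check minimizes the population
discrepancy sum_g n_g [ln|S(theta)| + tr(S(theta)^{-1} Sigma_g) −
ln|Sigma_g| − 2] over the reduced model and uses the minimum as the
noncentrality of a noncentral chi-square(1); simulation and approximation
agree within Monte-Carlo error across the tested grid. Default 2000
replicates (MC SE ≈ 0.009 near power 0.8); the acceptance run uses 5000.
Power curves hold e² fixed and move the remainder between A and C so every
grid point is a valid decomposition.

## Problem sizes and numerical conventions

Simulation-based checks use: 5000 replicates at 391 + 381 pairs for the
design-power result; 1000 replicates of 200 + 200 pairs for the
null-unbiasedness comparison; 500 replicates of 500 + 500 pairs for CI
coverage; 10 cohorts of 5000 + 5000 pairs for parameter recovery (the
single-draw sampling SD of a² at that size is ≈ 0.021, so recovery is
assessed on the replicate mean, a bias check with MC SE ≈ 0.007). Sample
SDs use the n−1 divisor; saturated ML moments use the n divisor (the ML
solution). LRT statistics are clipped at zero, with anything below −1e-4
treated as an optimization failure. Ties in the outlier rule are kept
(masking requires strictly |z| > threshold).

## Known limitations

Ordinal/threshold models, site or scanner random effects, G×E/rGE
extensions, assortative-mating corrections and simultaneous ACDE
estimation (unidentified in this design) are out of scope. P-values across
phenotypes in a batch are unadjusted; multiplicity control is left to the
consumer of the results table.
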