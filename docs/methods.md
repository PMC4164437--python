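# Methods

## Model

A biallelic marker's genotype G is coded 0/1/2 by allele count and treated
as an ordinal trinomial response; the q phenotypes y (continuous, binary or
ordinal, entered as numeric codes) are covariates of a cumulative-logit
(proportional odds) model:

    P(G <= 0 | y) = expit(alpha1 + beta' y)
    P(G <= 1 | y) = expit(alpha2 + beta' y),   alpha1 < alpha2.

The proportional-odds property — the covariate effect on the cumulative
log-odds is the same at both cut-points — is what lets one slope vector
summarise association across all three genotype classes. The assumption of
a *monotone* allele effect is implicit: a strongly over-dominant locus
violates the ordering the model exploits and will lose power here. No
covariate adjustment is supported; phenotypes are the only regressors.

Association is H0: beta = 0 against H1: beta != 0.

## Score test

Under H0 the MLEs of the intercepts have closed form: the cumulative
sample genotype proportions, gamma1 = p0, gamma2 = p0 + p1. Differentiating
the log-likelihood in beta at that null fit gives

    U = sum_i c(G_i) (y_i - ybar),
    c = (1 - gamma1, 1 - gamma1 - gamma2, -gamma2),

a contrast of phenotype sums across genotype classes; the weights satisfy
sum_i c(G_i) = 0 exactly, so U is location-invariant in y. Its null
variance is V = wbar * sum_i (y_i - ybar)(y_i - ybar)' with
wbar = sum_g p_g c_g^2, and

    T = U' V^{-1} U  ~  chi-square(q)  under H0.

The whole statistic is a function of genotype proportions and phenotype
moments — one pass per variant, no iteration. Correctness of the algebra
is pinned by an oracle test: U must equal the central-difference gradient
of the likelihood at the null MLE to 1e-6 relative tolerance on randomly
generated datasets (tests/test_acceptance.py, 100 instances).

Numerical choices:

* V uses the sum-of-squares form (proportions, i.e. 1/n, inside wbar; no
  n-1 correction). The n vs n-1 choice is asymptotically irrelevant and the
  type-I calibration study validates it at n = 2000.
* Singular V (collinear phenotype columns) is a hard error by default;
  `pseudo_inverse=True` switches to the Moore-Penrose inverse with
  df = rank(V).
* Monomorphic markers yield a flagged NA result (status "monomorphic"),
  never an exception, so genome scans proceed.
* Missing data: complete-case deletion per variant (any missing genotype or
  phenotype drops the subject for that variant); the dropped count is
  reported per variant.
* T is invariant to invertible affine maps of y and to allele relabelling
  G -> 2 - G (the weights map to their reversed negation); both are
  asserted as property tests.

## MLE and likelihood-ratio test

`GenotypePOModel.fit()` maximises the likelihood by Newton-Raphson with
analytic gradient and Hessian, starting from the closed-form null fit,
with step-halving (up to 30 halvings; a step not measurably worse than the
current point is accepted, because near the optimum the log-likelihood is
flat to machine precision while the gradient still contracts). Convergence
is a gradient max-norm below 1e-8, at most 50 iterations. Standard errors
come from the inverse observed information. A parameter-norm guard
(|beta| > 50) flags quasi-separation; the LRT is still reported from the
achieved likelihood.

When a genotype class is absent the corresponding intercept is not
identified: an empty boundary class sends alpha1 or alpha2 to +/-infinity,
and an empty heterozygote class makes the two intercepts coincide. The fit
then runs Newton on the identified parameters only, pinning the boundary
intercept at +/-36 (where expit saturates in double precision) or tying
the intercepts, which reduces the model to binary logistic regression on
the two remaining classes. Tests assert the reduced fits match
statsmodels' Logit and that the full-model fits match statsmodels'
OrderedModel and a brute-force grid search — independent maximisers, never
the implementation.

The LRT statistic 2(l1 - l0) is chi-square(q) under H0 and is
asymptotically equivalent to T; the test suite checks Spearman correlation
> 0.99 between the two p-value streams at n = 2000 and power differences
below 0.02 on the multivariate scenarios.

## Analytic power for case-control designs

For a dichotomous phenotype (case indicator), the disease model is a
single locus under Hardy-Weinberg equilibrium: allele frequency p gives
genotype frequencies q = ((1-p)^2, 2p(1-p), p^2); genotype relative risks
(1, R1, R2) and prevalence K give penetrances f_j = R_j f0 with
f0 = K / sum_j q_j R_j; and the genotype distributions in cases and
controls are g_j(case) = q_j f_j / K, g_j(control) = q_j (1-f_j) / (1-K).

With case fraction phi, pooled genotype distribution
p_j = phi g_j(case) + (1-phi) g_j(control), score weights c and wbar formed
from the pooled distribution, and Delta = sum_j (g_case_j - g_control_j) c_j,
the score statistic is asymptotically noncentral chi-square(1) with

    lambda = n phi (1 - phi) Delta^2 / wbar,

and power at level alpha is P(chi2_1(lambda) > chi2_1 critical value). The
noncentral tail uses scipy's `ncx2`, not a normal approximation. lambda is
linear in n, maximised over phi at 1/2, and invariant to allele
relabelling — all property-tested.

Risk presets follow the usual convention: recessive (1, 1, 1.5), additive
(1, 1.25, 1.5), dominant (1, 1.5, 1.5). The reference surface (twelve
(K, p, mode) cells at n = 2000, phi = 0.5) and its powers at alpha = 0.005
are frozen as golden values in the tests to four decimal places. Only the
case-control specialisation has this closed form; for other alternatives
the Monte-Carlo route through the simulators applies (the mean of T over
replicates estimates df + lambda, which is itself a test).

## Simulators

`simulate_case_control` draws multinomial genotype counts for n*phi cases
from g(case) and the rest from g(control); the phenotype is the case
indicator. `simulate_case_control_tables` produces the same law directly
as 2x3 count tables, which the binary-phenotype tests consume through
their sufficient statistics (the model supports frequency weights, so the
table path is exactly the expanded-vector path; a test asserts equality).

`simulate_multiphen` emulates a cohort with one QTL and three phenotypes:
G ~ Binomial(2, maf); residuals are trivariate normal with unit variances
and a single common pairwise correlation rE (equicorrelation, positive
definite for rE in (-1/2, 1)); each associated phenotype k (scenario I:
{1}, II: {1,2}, III: {1,2,3}) receives b_k * beta * (G - 2*maf) with
b1 = b2 = +1 and b3 = +/-1 switching the third phenotype's direction.
Centring G gives the slope a closed form in the variance explained:
beta^2 = ev / ((1 - ev) * 2 maf (1 - maf)).

Defaults n = 1000 and ev = 0.005 (0.5% of each associated phenotype's
variance) put power in the moderate range where method differences are
visible; they are package choices, since no canonical values attach to
these scenarios. Consequently the *absolute* power values of the
multiphenotype study are illustrative, not certified; the certified claims
are relative — Score and LRT agree, and inert direction switches change
nothing. What these generators do not emulate about real data: linkage
disequilibrium between markers, non-normal phenotype residuals,
ascertainment other than case-control sampling, covariate structure, and
genotyping error. Passing tests therefore demonstrate internal statistical
correctness, not robustness to those features.

## Study harness

Four reproducible studies (all pure functions of configuration and seed;
per-cell RNG streams are spawned from a SeedSequence keyed by the
parameters that actually affect the simulation, so cells differing only in
inert parameters are byte-identical):

* analytic surface (`reproduce_table1`) — the twelve-cell NCP/power table;
* type-I error (`type1_study`) — default 2,000 replicates of n = 2000 null
  case-control data over a (K, p) grid, nominal levels 0.1/0.01/0.005,
  four tests (Score, LRT, trend, Pearson); 10,000 replicates behind the
  `replicates` argument;
* power (`power_study`) — the same machinery under the alternative preset
  models, with the analytic score power alongside;
* multiphenotype power (`multiphen_power_study`) — Score vs LRT over the
  30-cell scenario grid (scenario I once, II/III under both b3 signs,
  rE in {0, 0.3, 0.7}, maf in {0.01, 0.40}), default 1,000 replicates.

Default replicate counts (2,000 / 1,000) keep a full regeneration of the
simulation studies within a few minutes on one core; they are arguments,
not constants.

## Comparators

Cochran-Armitage trend test (1 df, scores 0/1/2 by default, affine-score
invariant, no continuity correction) is implemented directly — its N*r^2
identity and statsmodels' (N-1)/N linear-by-linear statistic serve as
cross-checks. Pearson's chi-square (2 df, zero-margin columns dropped with
df reduced) delegates to scipy's `chi2_contingency` without correction.

## Known limitations

* Integer genotypes only; imputed dosages are rejected (the trinomial
  model does not apply).
* No covariates other than the phenotypes themselves.
* The proportional-odds assumption is untested per variant; a multinomial
  (non-proportional) logit alternative is out of scope.
* Multiple-testing control is raw p-values plus an optional Bonferroni
  column; nothing more elaborate.
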