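# Methods

## The model

`triofx` partitions variance in a focal family member's mental-distress
score into genetic components carried by the three members of a
mother-father-offspring trio. Writing `o` for the focal (direct) slot and
`m`, `p` for the two non-focal slots, the phenotype of family *i* is

    y_i = z_f(i)' b_o + z_a(i)' b_m + z_b(i)' b_p + x_i' beta + e_i

where `z_r(i)` is the standardized genotype vector of role *r* in family
*i*, the per-SNP effect triplets `(b_o, b_m, b_p)_j` are i.i.d. normal
with covariance `Sigma_g / M`, and `e_i ~ N(0, sigma2_e)`. Marginally,

    V = s2_o G_ff + s2_m G_aa + s2_p G_bb
        + s_om (G_fa + G_fa') + s_op (G_fb + G_fb') + s_mp (G_ab + G_ab')
        + s2_e I

with `G_rs = Z_r Z_s' / M` the empirical cross-role genomic-relatedness
blocks. Under random mating the diagonal expectation gives the variance
identity

    Var(y) = s2_o + s2_m + s2_p + s_om + s_op + s2_e

(the 0.5 parent-offspring kinship and the doubled cross terms cancel);
`s_mp` is estimated but contributes no phenotypic variance, and is
excluded from variance-share totals. As the focal role changes the same
decomposition is re-read: for an adolescent outcome the indirect slots
are mother- and father-driven effects; for a parental outcome they are
partner- and child-driven effects. Negative `s_om` means the same
variants act in opposite directions through the child's own genotype and
the rearing environment the mother provides — a gene-environment
correlation.

Five nested specifications are compared per focal individual: FULL (all
seven parameters), MO (`s2_o, s2_m, s_om, s2_e`), FO (`s2_o, s2_p, s_op,
s2_e`), DIRECT (`s2_o, s2_e`), NULL (`s2_e`). Selection is by minimum
AIC with ties broken toward fewer parameters; BIC and likelihood-ratio
tests against FULL are reported alongside. AIC counts only free
covariance parameters — the fixed-effect count is constant across the
five models, so rankings are unaffected.

## Estimation

Full maximum likelihood, not REML, is the primary criterion: the
AIC/BIC/LRT comparisons across models with identical fixed effects
require likelihoods on a common scale. Fixed effects are profiled out by
GLS at each parameter value.

The genetic 3x3 block is parameterized through a lower-triangular factor
restricted to each specification's free entries, so positive
semidefiniteness holds by construction while covariances keep free sign;
the residual variance is optimized on the log scale. Reported covariance
blocks can therefore never be negative definite — a deliberate departure
from an unconstrained fit, and the reason boundary estimates (a variance
pinned at zero) appear as exact zeros.

The optimizer is a damped Newton iteration: analytic gradients; the
average-information (AI) matrix pulled back through the factor
parameterization as the curvature metric, augmented with the exact
second-order chain term of the reparameterization (without it the metric
degenerates whenever a factor entry sits at zero, which is precisely
where boundary fits live); Levenberg-style diagonal damping with an
absolute floor; backtracking acceptance. Convergence requires a relative
log-likelihood change below 1e-8 and a gradient norm below 1e-4 times
the likelihood scale. Starts come from a Haseman-Elston-style moment
regression of the residual outer product on the component matrices
(computed on a family subsample above n = 800 — a start only needs the
right neighbourhood), with subsequent restarts jittered; `fit_model`
defaults to 5 restarts, and the replicated experiments use 1, which
reproduced the same optima in spot checks at a quarter of the cost. A
fit where no restart converges raises, carrying the best incumbent.

Likelihood-ratio p-values use a plain chi-square on the difference in
free parameters. With variances on the boundary this is conservative;
the comparison metadata flags it. Fits are cross-sectional per wave on
complete cases.

## The trait-based stage

For each focal role and each of five traits (anxiety, depression,
neuroticism, ADHD, anorexia nervosa), the repeated distress score is
regressed on the standardized polygenic scores of all three trio members
at once, adjusted for days since lockdown, focal age and child sex, with
a random intercept per focal person and — for adolescent outcomes — a
maternal-ID intercept for sibling clusters. The focal person's own
coefficient is labelled direct, the other two indirect. Estimation is
REML through `statsmodels` MixedLM (an optimizer cascade bfgs → lbfgs →
powell guards against line-search blow-ups at variance boundaries); all
rows with an observed outcome are retained, the likelihood-based
analogue of full-information estimation. A singular random-effects fit
is refit without the offending intercept and flagged; a vacuous sibling
level (no mother with two studied children) is dropped up front.
Interaction models add PGS x time products for all three scores, with
time centered at its sample mean first so main effects keep their
interpretation at the average questionnaire date. Wald 95% CIs use the
1.96 normal critical value.

Benjamini-Hochberg q-values are computed within each declared family of
five traits per (focal role, coefficient) pair; the family boundary is
configurable since reasonable alternatives (all 15 models at once)
exist.

## The synthetic cohort

The generator emulates the study design, not the population: n trios
with parents drawn as independent Hardy-Weinberg founders at MAFs
uniform on (0.05, 0.5), offspring by Mendelian transmission, a
`sibling_fraction` (default 0.1) of families re-assigned an existing
maternal cluster (sharing that mother's genotype), effect triplets from
`N(0, Sigma_g / M)`, and an AR(1) person-level residual across up to
three waves (lag-1 correlation 0.5). Item responses threshold the latent
score plus item noise (SD 0.3) at cutpoints 0.8/1.6/2.4, chosen to give
the right-skewed marginals that motivate the log transform; items and
whole waves are masked at 2% and 15%. Wave dates fall in biweekly
windows within the first 60 days after 2020-03-12. Covariate stand-ins:
child sex Bernoulli(1/2), ages normal with means/SDs typical of a
lockdown trio sample (16.9/0.6, 47.1/4.5, 49.4/5.1 years), ten
standard-normal dummies in place of genomic principal components, one
binary genotype-batch dummy, and a same-household flag (rate 0.95) for
the sensitivity restriction. Polygenic scores use one noisy weight
vector per trait shared across all family members, with per-SNP noise
calibrated so the squared correlation with the true genetic value equals
`pgs_r2` (defaults 0.10-0.20 by trait, the proxy quality typical of
current psychiatric scores); scores are standardized across the sample.

Deliberately absent: linkage disequilibrium (the estimand is defined on
standardized genotypes; LD is irrelevant to testing the estimator),
imputation and chip error, X chromosome, population stratification, and
assortative-mating equilibria — a rank-matching knob exists only to
demonstrate the direction of the bias assortment induces, not to model
it. Passing tests therefore show the estimators are correct under the
model's own assumptions; they do not show robustness to stratification
or assortment, which in real cohorts are absorbed into indirect-effect
estimates.

Default truth values follow the adolescent scenario: direct 8.8% and
maternal indirect 10.4% of variance, direct-maternal correlation -0.13
(so `s_om = -0.013`), residual 0.82.

## Numerical and design choices

* Genotype standardization uses generating allele frequencies when
  simulating (removing an inconsequential estimation layer from tests)
  and founder-sample frequencies otherwise; SNPs with founder MAF below
  0.01 are excluded with a logged count. Monomorphic SNPs are an error
  naming the indices.
* The unrelatedness filter greedily drops the higher-indexed family of
  any cross-family pair whose maximum absolute relatedness over all six
  blocks exceeds the threshold (default 0.05, appropriate for
  genome-wide M; desk-scale cohorts with small M need a threshold above
  the 1/sqrt(M) noise floor). Within-family relatedness never triggers
  removal.
* Log transform of SCL-5 scores uses the natural log; standardization
  makes the base immaterial. Standardization is within (focal group,
  wave) for lockdown analyses and within the pooled sample for the
  overall adolescent score (marked wave 0). A zero-variance or
  under-filled stratum raises instead of emitting NaN.
* An indefinite assembled covariance (possible only through numerical
  degeneracy) gets a single logged 1e-8 ridge, never silently.
* All randomness flows from per-stage streams spawned off one seed;
  pipeline result tables are byte-identical across reruns (the manifest,
  which records wall-clock timings, is the one non-deterministic file).

## Problem sizes in the validation suite

Replicated experiments run at n = 2000 trios, M = 2000 SNPs, 20
replicates for parameter recovery and model selection (recovery means
land within ±0.03 of truth; the generating model wins the AIC comparison
in a majority of replicates, and NULL-truth data select NULL or a
near-zero DIRECT in ≥80%). Each replicate's genotype draw — and hence
its relatedness structure — is independent of the generating truth, so
the selection study builds it once and shares it across scenarios; the
per-scenario fits are unchanged by the sharing. Trio-PGS coefficient recovery uses n = 2000
families over three waves; the BH error-control experiment uses 200
replicates of a fixed n = 120 design with fresh null outcomes, a size at
which Wald p-values are already well calibrated. Grid-search optimality
checks run at n ≤ 60 where dense brute-force evaluation is exact. The
acceptance script reruns the same computations at n = 1500 / 6
replicates, its own choice of compact scale.

## Known limitations

Point estimates only for variance components (no standard errors or
bootstrap), matching the model-comparison-centred design. The AI metric
is an approximation away from the optimum; the damping schedule, not the
metric, guarantees monotone progress. The five-model AIC comparison
inherits AIC's known tendency to admit an occasional overfit extension
(one extra component clears the 2-units-per-parameter bar ~15% of the
time under the null), visible in the selection experiments. FULL-model
`s_mp` is weakly identified — under random mating its design matrix has
near-zero diagonal — so its estimates are noisy at desk scale.
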