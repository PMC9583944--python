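# Methods

This note documents the statistical models, the numerical choices, and the
design decisions behind `gxeblup`, and states what the synthetic-data
benchmarks do and do not demonstrate.

## Phenotype model

Records are trial-by-season observations of a single quantitative trait on
genotyped individuals. Before model fitting, phenotypes are divided by
their trial-by-season standard deviation so that variance heterogeneity
between cells does not masquerade as genotype-by-environment interaction
(G×E); the scale factors are retained for back-transformation. The linear
mixed model is

y = Xb + Σ_q Z_q u_q + Z_p u_p + e

* **Fixed effects** `Xb`: trial-by-season cell means (or season means in
  single-trial models), treatment-coded with an intercept. Significance is
  assessed with Wald chi-square tests on the coefficient block.
* **Genomic terms** `u_q`: var(u_q) = Σ_q ⊗ G_q. The environment covariance
  Σ_q is defined over *genomic environments*: groups of trial-by-season
  cells within which the effect has homogeneous variance and correlation 1.
  Available structures: single variance with correlation 1 (`uniform`), one
  variance independent across environments (`iid`, the classical univariate
  interaction term), heterogeneous diagonal, factor-analytic ΛΛ'+Ψ with
  lower-triangular Λ (sign convention: first non-zero loading per factor is
  non-negative), and unstructured.
* **Permanent environment** `u_p`: one level per individual-by-trial with a
  variance per trial, capturing the persistent non-genetic effect of a
  tree's planting position across seasons. Residual variances are likewise
  grouped by trial. Both groupings reflect the observation that these
  variances differ between trials but not between a trial's seasons.

## Genomic relationship matrices

Additive GRMs use the centred cross-product form G = ZZ'/(2Σp_j q_j) with
Z the dosage matrix minus twice the allele frequency (VanRaden's first
method). Dominance GRMs code genotype classes (0, 1, 2 alt alleles) as
(−2p², 2pq, −2q²) and scale by Σ(2p_j q_j)², a parameterisation with zero
mean and zero covariance with the additive contrast under Hardy–Weinberg
proportions. Allele frequencies default to the panel the GRM is built from
but can be supplied, which is how single-trial GRMs (local frequencies,
local individuals) and all-individual GRMs are distinguished. Monomorphic
loci have undefined 2pq scaling and are dropped with a warning. QTL and
background GRMs are built on the disjoint locus sets inside and outside a
supplied physical interval. Near-singular GRMs are *bent* before fitting:
eigenvalues floored at ε (default 10⁻⁶) and the matrix reconstructed —
the algorithm behind bending is not prescribed anywhere authoritative, so
eigenvalue clipping was chosen and is recorded on the GRM object.

## REML estimation

The restricted likelihood is maximised on the dense observation-level
covariance V = Σ_t Σ_t[env_i, env_j]·K_t[level_i, level_j], which is the
right regime for ~10³ records (every fit in the package is dense algebra;
no sparse mixed-model-equation iteration). Updates are average-information
(AI) steps with:

* a step-halving line search accepting only non-decreasing log-likelihoods,
  so the trajectory is monotone;
* projection of candidates onto the parameter space — variances ≥ 0,
  specific variances ≥ 0, unstructured Σ projected onto the PSD cone by
  eigenvalue clipping (an unconstrained Σ can otherwise wander into
  indefinite matrices that still give a factorisable V and a spuriously
  high likelihood);
* pinning of components at the zero boundary when their gradient points
  outward (they re-enter if the gradient reverses);
* a damped, then scaled-gradient, fallback when the AI direction fails.

Convergence is declared when the log-likelihood improves by less than 10⁻⁹
(parameter drift along flat ridges of over-parameterised structures must
not block convergence). Starting values split half the phenotypic variance
equally among the random terms, with the other half on the residual.
Unstructured terms are warm-started from a factor-analytic FA(q−1)+Ψ
pre-fit: the element-wise unstructured update crawls when the optimum lies
on the singular boundary of the covariance cone (environment correlations
near 1), while the FA parameterisation reaches that boundary smoothly; from
the FA solution the unstructured fit typically converges in one step.
`max_iter=0` evaluates the model at supplied parameter values, which is how
BLUP/PEV extraction is tested against a dense Henderson-equation solve.

BLUPs and prediction-error variances for any individual × environment —
including unphenotyped individuals present in the GRM — come from
û = C'Py and PEV = var(u) − C'PC with C the covariance between the effect
and the data and P the REML projection matrix. Sums of terms (total =
additive + dominance) use the same projection, so posterior
cross-covariances are included in the PEV of the sum.

AIC = −2·logL + 2·k with k the number of covariance parameters; by default
boundary-pinned parameters are still counted (convention switchable to
`free`, and the pinned flags are recorded per parameter in the fit).
Variance components are tested with likelihood-ratio statistics clipped at
zero and referred to the binomial 50:50 chi-square mixture for parameters
on the boundary of the parameter space; the default significance threshold
for these tests is p < 0.01.

## Model-selection strategy

The strategy fits, in order: single-trial univariate models testing
genomic-by-season interactions (STGWU); single-trial multivariate models
with Ward-guided season merging where interaction is significant (STGWM);
a multi-trial univariate model on the combined data with the
all-individual GRM (MTGWU); multivariate multi-trial models (MTGWM);
the QTL + background split with tests of QTL×environment and dominance-QTL
components (MTQBU); and a final multivariate QTL + background merge pass
(MTQBM). Design decisions taken where the procedure was open:

* **Test order within univariate stages**: the dominance interaction is
  tested and eliminated before the additive interaction. In
  family-structured panels the additive and dominance interaction terms are
  strongly collinear (within an F1 family both GRMs are nearly constant
  blocks), so marginal drop-one tests from the full model have little
  power; sequential backward elimination restores it.
* **Multivariate structure**: unstructured for ≤3 environments (a
  factor-analytic structure is not more parsimonious there),
  factor-analytic from 4 environments up, starting at order 1 and
  increasing while the likelihood-ratio test against the lower order is
  significant.
* **Merge search**: candidate environment maps follow dendrogram merge
  order from Ward clustering of d = √(2(1−r)) on the effect's genomic
  correlation matrix; a merge is kept when the constrained model is not
  significantly worse; the search stops after two consecutive rejections.
  Cross-trial merges can only arise at multi-trial stages because
  single-trial stages see one trial.
* Every fitted model, comparison and accept/reject decision is recorded;
  the strategy is deterministic given data and configuration.

## Prediction accuracy

Expected accuracy per effect, trial-by-genomic-environment and cohort is
r_E = √(1 − σ̄²/v) with σ̄² the cohort-mean PEV and v the effect variance in
that environment; cells with the variance pinned at zero are flagged
instead of reported. Cohorts per target trial-environment: tested in it
(TGE), tested in the trial but other environments only (trial-tested),
tested only elsewhere (trial-untested; genotyped individuals with no
records anywhere are counted here). The accuracy equation is implemented
with the square root, the standard reliability form.

Realised accuracy masks each validation fold's phenotypes, refits the model
with the full GRM (reference plus validation individuals), and correlates
predicted genomic values with *adjusted phenotypes* — permanent-environment
BLUP plus residual from a genomic-term-free model — then divides by √h²
(additive predictions) or √H² (total) from the most parsimonious model.
Fold assignment is stratified by population (XTCV, the new-accession
scenario, masking all of an individual's records) or by trial (WTCV,
masking only the records in the sampled trial). Accuracy is computed per
trial-by-genomic-environment within fold and averaged over folds, with the
fold SD retained. The cross-validation report also carries the PEV-based
expected accuracy *of the masked cohort from the same refit*: that is the
model-consistent counterpart of the realised value (the whole-data TGE
expectation conditions on the individual's own records and is systematically
higher), and the pair should agree on average exactly when the data come
from the fitted model class.

## Synthetic data

The generator realises the data-generating process the models assume:

* **Founders**: Balding–Nichols — per-population allele frequencies drawn
  Beta around common ancestral frequencies (uniform on 0.1–0.9) with the
  divergence parameter equal to the target F_ST; haplotypes Bernoulli.
* **Families**: F1 offspring from recombinant founder gametes (Haldane
  model, Poisson crossovers, uniform 1 cM / 200 kb map, no interference);
  F2 families self a single simulated F1. Evenly spaced physical positions
  over 8 chromosomes of 30 Mb.
* **Effects**: Gaussian per-locus effects, calibrated *in expectation* —
  drawn with variance truth/denominator of the corresponding GRM, so the
  relationship-scaled component variance equals the truth value. QTL
  additive effects live on the interval loci; background additive effects
  combine factor and specific genomic deviates to give the environment
  covariance Λ_true Λ_true' + Ψ_true; dominance uses the orthogonal
  heterozygosity coding.
* **Phenotypes**: cell mean + additive(environment) + dominance +
  permanent-environment draw per individual-by-trial + residual draw per
  record, under an arbitrary (unbalanced) assessment plan.
* One master seed feeds named child streams; identical configuration and
  seed reproduce every file byte for byte.

`study_like_config` emulates the motivating study's scale: three divergent
populations (target pairwise F_ST 0.10), nine F1 families evaluated in two
overlapping trials, six F1 families in a third trial and twelve F1 + three
F2 families in a fourth, ten trial-by-season cells with Table-like overlap
fractions, ~4,500 SNPs with an 8-SNP QTL interval on chromosome 4, and
truth variances of the magnitude of the fitted study components (QTL
additive 0.26, background 0.45–0.98 with a weakly-correlated pair of
late-trial seasons, dominance 0.12, per-trial permanent-environment and
residual variances). Benchmark scenarios (`recovery_dataset`,
`two_trial_dataset`) fix the conditions for parameter recovery
(vAQ = 0.25, vAB = 0.60, vDW = 0.10, vU = 0.05, vR = 0.30; 2,000 SNPs;
~600 records as 200 individuals × 3 seasons), for selection-strategy power
(600 records over two trials; the divergent scenario gives the last cell a
background correlation of 0.05 with the main group), and for accuracy
properties (a three-environment truth with pairwise correlation 0.5, and a
noise-free limit with 100 loci so the training set over-determines the
genomic space).

What the generator does *not* emulate: selection or multi-generation
breeding, genotyping error and missingness patterns of real arrays,
non-Gaussian effect distributions (a mixture at the QTL, say), spatial
field trends, or assessment-protocol differences between trials. Passing
benchmarks therefore demonstrate internal consistency — the estimators
recover the parameters of the assumed model class at realistic sizes — not
robustness to the ways real orchard data violate that class.

## Problem sizes and tolerances

Simulation-based checks use 6–20 replicates at 400–1,000 records per fit;
the replicate counts and sizes were chosen so the full suite and the
acceptance script each run in minutes on a single core while keeping
Monte-Carlo error well below the tested effect sizes. Statistical
assertions use 3 empirical standard errors for parameter-recovery means,
rate thresholds (≥90% null-collapse, ≥80% divergent-isolation) for the
strategy, a ±0.1 band on the mean realised-minus-expected accuracy gap
(about 2 standard errors of that mean at the benchmark sizes), and 10⁻⁶ /
10⁻⁸-level tolerances against the closed-form oracles. Deterministic
arithmetic (heritability identities, biplot reconstruction, Woodbury
identities) is checked to 10⁻¹⁰ or better.

## Known limitations

* The dense-V likelihood scales as n³ per iteration; beyond ~5,000 records
  a sparse MME formulation would be needed.
* Dominance and additive components separate poorly in panels dominated by
  a few large full-sib families; estimates are exchanged between the two
  terms (their sum is stable), which also motivated the sequential
  interaction-testing order.
* The permanent-environment variance is weakly identified with only two
  seasons per trial and is boundary-censored in small samples.
* Expected-accuracy cohort comparisons across trial-environments can
  invert when a genomic environment spans trials (an individual "untested"
  in the target trial may be tested in the same genomic environment
  elsewhere); within a trial-environment the cohort ordering holds.
* LOESS smoothing of LD decay uses a locally-quadratic tricube smoother
  with span 0.3 by default; the span is a configuration knob because no
  authoritative value exists.
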