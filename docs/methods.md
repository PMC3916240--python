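# Methods

## The statistical problem

On the non-pseudoautosomal X chromosome men carry one allele where women
carry two, and random X-chromosome inactivation (XCI) silences one female
copy at most loci. A locus that is fully dosage-compensated behaves, for a
quantitative trait standardized within sex, as if hemizygous men were
homozygous women: coding male genotypes {0, 2} and female genotypes
{0, 1, 2} makes the sex-specific regression slopes equal
(b_F = b_M). At a locus that escapes XCI both female copies are active, so
on the same coding the female slope is twice the male slope (b_F = 2 b_M).
This factor-of-two contrast drives everything in the package: the
association codings, the sex-differentiated and heterogeneity tests, the
Bayesian model comparison, the per-sex variance-explained formulas, and the
male scalings of the X genetic relationship matrix.

## Male genotype codings

Raw male genotypes are stored as allele counts in {0, 1} (hemizygous
truth); the analysis coding is applied at regression time and tagged on
every male estimate:

- `slope02`: males coded {0, 2}. The slope is half the hemizygote class
  difference. This is the reporting scale for summary statistics and the
  scale the dosage-compensation priors are written on.
- `per_copy`: males coded {0, 1}. The slope is the full per-allele effect
  (2 × the slope02 slope; the SE doubles too, so z and p are identical).

Functions that are sensitive to the factor of two (`posterior_ndc`,
`per_copy_effect_combined`) refuse a wrongly tagged male input instead of
rescaling silently; a silent factor-of-2 error is exactly the failure mode
the tags exist to prevent.

## Association model

Per sex and SNP, a simple linear regression of the inverse-normal
transformed residual trait on coded dosage (expected counts for imputed
data), with missing pairs dropped per SNP. p-values use the normal
reference z = β/se rather than the t distribution, matching the
large-sample behavior of standard GWAS engines; at the sample sizes the
filters admit (MAC > 3 and n ≥ 10) the difference is negligible for the
pipeline's purposes. Variant QC keeps a SNP when female imputation info
> 0.4 and female minor allele count > 3, both strict inequalities. For
imputed data the MAC is the rounded expected count; whether the original
filters used hard or expected counts is not documented anywhere we know of,
and the rounded expected count is the convention here.

## Phenotype preparation

Traits are residualized on covariates by OLS (intercept always included)
and the residuals are mapped to normal scores by the rank-based inverse
normal transform with Blom offsets, Φ⁻¹((r − 3/8)/(n + 1/4)), ties sharing
the average rank. Blom offsets are the common GWAS choice and make the
transform deterministic; other offset families differ by O(1/n) and do not
move any statistic in this package materially. Both steps run within sex by
default so each sex ends with mean 0, sd ≈ 1. Constant (or numerically
constant, range ≤ 1e-10 relative) residual vectors are an error: the
transform is undefined, and a constant residual usually means the trait
leaked into the covariates. Rank-deficient covariate matrices are rejected
with the offending columns named.

## Meta-analysis

Fixed-effects combination is inverse-variance weighting:
β = Σwᵢβᵢ/Σwᵢ, se = (Σwᵢ)^(−1/2), wᵢ = seᵢ⁻². The sex-differentiated test
is χ² = z_F² + z_M² on 2 df (1 df with a flag when one sex is missing); the
sex-heterogeneity test is the two-sample Wald statistic
q = (b_F − b_M)²/(se_F² + se_M²) on 1 df, algebraically equal to Cochran's
Q for two strata. Genomic control uses λ = median(χ²)/0.4549364 (the exact
χ²₁ median) and divides statistics by λ only when λ > 1 — deflation is
never applied. The pipeline driver orders the stages as the multi-cohort
design requires: GC within each cohort × sex stratum (implemented as
se × √λ), fixed-effects meta within sex across cohorts, then the
2-df and heterogeneity tests on the per-sex meta results; SNPs present in
fewer than two strata are dropped.

## Dosage-compensation model comparison

The sampling distribution of (b̂_F, b̂_M) is approximated as normal with the
reported SEs. Each model puts a perfectly correlated normal prior on the
true effects, b_M = c·b_F with c = 1 (FDC) or c = 1/2 (NDC) and
b_F ~ N(0, s²). Integrating the shared effect analytically gives the
marginal likelihood as a zero-mean bivariate normal with covariance

    [[ s² + se_F²,  c s²        ],
     [ c s²,        c² s² + se_M² ]]

The prior scale solves P(2p(1−p) b_F² < 0.01) = 0.95 under b_F ~ N(0, s²):
s = √(0.01/(2p(1−p)))/1.959964, with p the combined-sample effect-allele
frequency (sex-specific frequencies differ in the third decimal and move
the posterior by < 0.001). For a zero-mean normal the two-sided quantile
form is exactly the solution of the probability equation, so no numerical
solve is needed. The Bayes factor is exp(logML_NDC − logML_FDC) and the
posterior follows from Bayes' rule with configurable prior odds (default
equal), computed on the log-odds scale so extreme Bayes factors cannot
overflow. The quadrature cross-check in the test suite integrates the
shared effect numerically (log-space, window centered on the analytic
posterior mode) and agrees to < 1e-6 over 1000 random draws.

Partial escape (0 < c⁻¹ − 1 < 1), priors with correlation below 1, and
per-tissue XCI are out of scope.

## Variance explained and sexual dimorphism

With the {0,2}/{0,1,2} coding the genotype variance is 2P(1−P) in women and
4P(1−P) in men, so variance explained must be evaluated per sex:
2P(1−P)b_F² and 4P(1−P)b_M². Sex-specific allele frequencies from the
summary rows are used for each cell. For an XCI-escaping SNP with per-copy
effect b (both sexes) and allele frequency f_a, the male mean shifts by
f_a·b and the female mean by 2f_a·b, so the male-minus-female difference
changes by −f_a·b relative to a population monomorphic for the major
allele; dividing by the observed sex difference gives the fraction of
dimorphism attributable to the SNP.

## X-aware GREML

Per-SNP standardization uses the pooled allele frequency counting each male
allele once: females (x − 2p)/√(2p(1−p)), males (x − p)/√(p(1−p)). Male
standardized rows are then scaled by √2 (FDC), 1/√2 (NDC) or 1 (EV), chosen
from first principles so the male genetic variance implied by the GRM is
2×, 0.5× or 1× the female one — the GRM-level counterpart of the genotype
variance argument above. GRM = (1/m)·DWWᵀD; SNPs with pooled MAF ≤ 0.01 or
monomorphic are skipped. The EV fit keeps a single residual variance for
both sexes; per-sex residual variances are a known limitation, not
implemented.

Relatedness pruning is greedy and deterministic: while any |off-diagonal|
exceeds the threshold (default 0.05), drop the individual in the most
offending pairs, breaking ties toward the larger index. The result is
guaranteed pairwise-clean but is not a maximum independent set; for GWAS QC
the determinism matters more than squeezing out a few extra samples.

REML maximizes the restricted likelihood of y = Xb + Σ g_k + e,
var(g_k) = σ²_k A_k, var(e) = σ²_e I, by average-information updates with a
single EM step whenever the AI step leaves the feasible region, components
floored at 1e-8 × var(y). Convergence requires the log-likelihood change
below `tol` (default 1e-8) and near-zero gradients (boundary components may
keep a negative gradient). SEs come from the inverse AI matrix; h² SEs by
the delta method. A singular information matrix (e.g. a GRM
indistinguishable from the identity, which aliases with the residual) flags
the fit as non-converged instead of raising. The test of zero X-linked
variance is the boundary LRT: p = ½·P(χ²₁ > 2Δll), so Δll = 0 gives p = 0.5.
The reported restricted log-likelihood omits the constant −½(n−p)log 2π;
only likelihood differences are ever consumed.

## Synthetic data: what it does and does not emulate

`simulate_genotypes` draws female genotypes Binomial(2, maf) (HWE) and male
alleles Bernoulli(maf), independently across SNPs; `simulate_phenotype`
adds Σ bᵢgᵢ (female scale) with male per-copy effects 2b (FDC), b (NDC) or
√2·b (EV) plus Gaussian noise. The √2 EV convention is one consistent
generative choice that makes the male and female genetic variances equal;
the EV estimation model is usually stated only at the GRM level, so the
generator had to fix a convention. One global seed drives all draws through
deterministically spawned substreams; runs are bit-reproducible.

Deliberately absent: linkage disequilibrium (every implemented statistic is
per-SNP, or in GREML's case insensitive to LD given the simulated
architecture), imputation-uncertainty structure beyond a carried info
column, relatedness/pedigree structure, pseudoautosomal regions, and
sex-differential residual variances. Tests passing on this generator
therefore validate the estimators' contracts under their own assumptions;
they do not probe robustness to LD pruning choices, cryptic relatedness or
imputation error in real cohorts.

## Problem sizes used in the checks

Slope-recovery and simulation-closure checks use 50,000 samples per sex at
a single SNP (Monte-Carlo error on a slope ≈ 0.005); the null type-I-error
check uses 2,000 SNPs at n = 600 females; genomic-control calibration uses
10,000 null statistics; REML recovery uses n = 2,000 (1,000 per sex),
m = 1,000 EV-model SNPs and h²_X = 0.30, asserting recovery within 2 SE.
These sizes put each Monte-Carlo band well inside the asserted tolerance
while keeping the whole suite under a couple of minutes.
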