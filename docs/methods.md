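# Methods

## Reverse regression

At each SNP the imputed dosage `G_i = pAB_i + 2·pBB_i` (expected count of
the chosen effect allele) is regressed on the J phenotypes:

```
G_i = α + Σ_j β_j y_ij + ε_i,   ε_i ~ N(0, σ²)
```

The fit is ordinary least squares via the normal equations; `σ̂²` is the
**maximum-likelihood** estimate RSS/n (not the unbiased RSS/(n−k)). This
choice is required for the likelihood-ratio construction of the joint test
and slightly changes absolute BIC values relative to an REML convention;
ΔBIC rankings at fixed n are unaffected. The coefficient covariance is the
`σ̂²(X'X)⁻¹` sub-block for the phenotype columns, i.e. also on the ML
scale. The J-df joint test is `χ² = 2(ℓ_full − ℓ_null) = n·log(RSS₀/RSS₁)`
against the upper tail of χ²_J.

Treating a genotype dosage as Gaussian is of course an approximation — the
underlying variable is a (possibly fractional) count in [0, 2] — but the
test only needs the least-squares machinery, and its null calibration is
checked empirically (see below). The Gaussian linear form is implemented
exactly; ordinal/multinomial reverse regression is out of scope.

### Phenotype handling

- **Complete cases are fixed across subsets.** For one SNP, individuals
  missing the dosage or *any* of the J phenotypes are dropped before any
  subset is fitted. BICs computed on different n are not comparable, so
  this is the only coherent way to run the subset search.
- **Categorical phenotypes** enter as numeric predictors: binary traits as
  their 0/1 codes, discrete traits with more than two observed levels as
  level indicators (first level dropped). The indicator columns count as
  parameters in the BIC.
- **Covariates** (age, sex, principal components) are not modelled inside
  the association equation. The recommended workflow is to replace
  phenotypes by residuals after covariate adjustment; `--residualize` on
  the command line does exactly this, per phenotype, with an intercept.
  A confounder that may itself share genetic effects (e.g. BMI when
  analysing waist-hip ratio) should instead be added as an extra phenotype
  column.
- **Degenerate SNPs** (monomorphic, all-missing, collinear designs) are
  emitted as NA rows with a reason string, never silently dropped, so
  per-study row sets stay alignable across studies.

## BIC subset dissection

For every subset S of phenotypes, `BIC(S) = −2ℓ̂_S + k·log(n)` with
`k = (#predictor columns in S) + 2` (intercept and σ²). All 2^J subsets
are enumerated (guarded at J ≤ 20) and reported as `ΔBIC = BIC(S) −
BIC(∅)`, so the null model anchors at 0 and negative values indicate
support for association. The best subset is the BIC minimiser; exact ties
resolve to the smaller subset, then lexicographic order, deterministically.

## Meta-analysis

Per-study effect vectors are pooled by multivariate fixed-effects GLS with
inverse-covariance weights (the standard form of the synthesis of
regression slopes):

```
V_pool = (Σ_k V_k⁻¹)⁻¹       β_pool = V_pool · Σ_k V_k⁻¹ β̂_k
```

The pooled test is the J-df Wald statistic `β'V⁻¹β`. Exact consequences
used as tests: a single contributing study passes through bit-identically
(the code short-circuits the double inversion in that case and carries the
study's own χ²/p forward when no genomic-control inflation was applied);
a duplicated study halves the covariance and doubles the Wald statistic;
pooling is invariant to study order and associative.

Per-subset ΔBICs are **summed** across studies: log-likelihoods of
independent samples add, and each study's `k·log(n_k)` penalty is already
inside its own BIC. SNPs present in only some studies are pooled over the
available ones, with the study count and total n reported. Studies with a
singular covariance at a SNP are excluded for that SNP with a logged
reason.

### Allele alignment

Studies are matched on (chromosome, position). The first study defines the
reference orientation; an entry with the allele pair swapped has β negated
and EAF complemented (V is unchanged); pairs matching only after strand
complement are re-oriented the same way; incompatible pairs are dropped
with a logged reason. Strand-ambiguous (A/T, C/G) SNPs are kept but
flagged — no frequency-based auto-flip — with a `--drop-ambiguous` switch.

### Genomic control

`λ = median(observed χ²) / median(χ²_J)`. Wald statistics `β'V⁻¹β` are
used at both levels so that inflating V by λ rescales the statistics
coherently (at the study level the stored test is the LRT; LRT and Wald
are asymptotically equal and the substitution is intentional). V is
multiplied by λ only when λ ≥ 1. Study-level correction followed by
meta-level correction gives the "double" control; the meta-level λ is
always reported, corrected or not. By default λ is estimated from the
input statistics; `--lambda-override STUDY=VALUE` accepts precomputed
values. A heterogeneity statistic is deliberately not reported: none is
defined for this pooling scheme here, and emitting a nonstandard one by
default would invite misreading.

## Synthetic data

The generator runs **forward** (genotype → phenotype), which is what makes
parameter recovery by the reverse analysis meaningful:

- genotypes: `g ~ Binomial(2, MAF)` under Hardy-Weinberg equilibrium;
- phenotypes: `y_i = g_i·b + e_i`, `e ~ MVN(0, R)` with unit variances, so
  `b` is a per-allele shift in phenotype SD units;
- imputation uncertainty: probability triples are the one-hot truth
  blended with a Dirichlet(1,1,1) draw, `p = (1−w)·onehot + w·dirichlet`;
  `w = 0` gives hard calls with info score exactly 1;
- at most one SNP per study carries the effect (SNPs are otherwise
  independent draws); multi-locus architectures, LD between SNPs and
  population stratification are *not* simulated — genomic control is
  instead exercised by directly injecting a known inflation into the
  statistics.

All randomness flows through one seeded generator; outputs are
byte-identical for a fixed configuration. Because real cohorts have LD,
relatedness, stratification and non-Gaussian traits, passing these
simulations demonstrates correctness of the computations and calibration
under the stated model, not robustness to everything field data can do.

## Study conditions used by the checks

- **Oracle agreement**: 100 random instances, n ≤ 200, J ≤ 5, against an
  independent pseudo-inverse normal-equations fit, at 1e-8.
- **Null calibration**: one null scan of 5,000 SNPs, n = 1,000, J = 4,
  compound-symmetric phenotype correlation 0.5, MAF 0.3 — rejection rates
  at α = 0.05/0.01 within 99% binomial intervals, KS uniformity, and
  λ ∈ [0.9, 1.1]; a ×1.5 inflation injected into every statistic must be
  recovered by λ and undone by double correction.
- **Subset recovery**: effect b = 0.25 SD on phenotype 1 of 4, MAF 0.3,
  n = 2,000, 200 replicates, two independent studies per replicate. The
  residual correlation here is the **identity**, by design: with correlated
  residuals the population reverse-regression coefficient `Σ_y⁻¹cov(y,G)`
  is nonzero for *every* phenotype (conditioning on the causal trait makes
  the others informative about the genotype), so "recover {phenotype 1}"
  is only a well-posed statement when the nuisance residuals are
  uncorrelated with the causal one. Recovery is asserted at ≥ 80% per
  study, and pooled two-study selection must do at least as well.

These sizes make the whole test suite and the acceptance script run in
seconds on one CPU while keeping every Monte-Carlo tolerance comfortably
wider than the corresponding standard error.

## Numerical and format choices

- Probability triples must sum to 1 ± 0.02; a sum below 0.1 marks the
  genotype missing (common practice for this format; the triples `0 0 0`
  denote no-calls).
- Both five-column GEN dialects (SNP-id-first and chromosome-first) are
  accepted; the detected dialect is recorded and preserved on write.
  Gzip is detected by magic bytes, not extension. Positions are 1-based.
- The info score is the IMPUTE-style ratio measure
  `1 − mean(f − e²) / (2θ(1−θ))` with `e` the expected dosage, `f` the
  expected squared dosage and `θ` the allele frequency; it is 1 exactly
  for hard calls, clipped below at 0, undefined (and treated as filtered)
  for monomorphic SNPs, and invariant to the choice of effect allele.
- Output files print floats with 6 significant digits in a fixed column
  order, so scans and meta-analyses are byte-deterministic given inputs
  and flags. Summary files open with `## key=value` header lines carrying
  the study id, phenotype list and tool version; the meta tool refuses to
  pool files whose phenotype lists differ in content or order.
- X-chromosome dosages are treated like autosomal ones (no sex-specific
  coding); this is a known gap.
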