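# Methods

This note documents the statistical models implemented in `generank`, the
synthetic data they are exercised on, the numerical choices, and the known
limitations.

## SNP-level association

Each SNP is tested by ordinary least squares of the phenotype on its allele
dosage (0/1/2, additive coding, no standardization — betas are per-allele so
their *sign* is comparable across cohorts) plus covariates: sex, age, the
first ten genetic principal components and, for a subscale phenotype,
optionally the other subscale. Two-sided p-values come from the t
distribution with n − k − 2 degrees of freedom (k covariates, plus intercept
and dosage). Monomorphic SNPs (dosage variance < 1e-12) are flagged
untested, kept in the output, and excluded from all downstream aggregation.
Rows with missing phenotype or covariates are dropped listwise.

`residualized_fast_gwas` residualizes the phenotype and every dosage column
against the covariates once (QR projection) and computes the per-SNP t from
the residual correlation. By the Frisch–Waugh–Lovell theorem this equals the
full fit; the test suite asserts agreement within 1e-8 on random instances.
This path is what the permutation engine re-evaluates per permutation.

The genomic inflation factor is λ = median(χ²)/0.4549364, where χ² is the
1-df deviate of each two-sided p and 0.4549364 the χ²₁ median. Under heavy
LD λ is a noisy estimator: with 5000 SNPs in rho = 0.8 blocks of ten its
null standard deviation is ≈ 0.027 (mean 1.00 across seeds), so single-run
values in roughly [0.95, 1.05] are expected behaviour, not drift.

## Cross-cohort sign-test replication

SNPs with combined-sample p strictly below a threshold (defaults 0.05, 1e-3,
1e-5) are greedily clumped: take the most significant remaining SNP as a
lead, discard candidates with r² ≥ 0.5 to it (r² = squared Pearson dosage
correlation on the combined sample), repeat. For the surviving leads the
sign of beta is compared between the two cohorts; leads missing or with an
exactly zero beta in either cohort are excluded with a warning (a zero sign
is undefined and a measure-zero event on continuous data). The concordance
rate k/n is reported with the exact Clopper–Pearson interval — the
degenerate k = n lower bound is (α/2)^(1/n), which reproduces the printed
2.500% (1/1) and 15.811% (2/2) bounds and identifies the exact interval over
Wald/Wilson alternatives — and with the right-tailed exact binomial sign
test P(X ≥ k), X ~ Bin(n, ½).

A caveat worth knowing: when leads are *selected by the combined-sample
p-value*, cross-cohort sign concordance exceeds ½ even under the global
null, because conditioning on combined significance favours SNP draws in
which both subsamples lean the same way (we measure ≈ 0.95 at the 0.05
threshold under a pure null). The pipeline implements the selection scheme
as designed; the package's own null-calibration test therefore selects leads
with threshold 1.0, where selection is independent of the cohorts and the
rate is genuinely ½ with a uniform sign-test p.

## Gene-level statistics

SNPs are assigned to a gene when their position lies within the gene bounds
extended by a 10 kb flank on both ends, inclusive; overlapping genes share
SNPs. Eight statistics combine a gene's SNP p-values under its LD matrix R
(signed dosage correlation estimated on the analysis sample):

| statistic | definition |
|---|---|
| minp | min pᵢ (uncorrected) |
| sidak | 1 − (1 − min p)^k |
| km_fisher | T = −2Σln pᵢ; E = 2k; Var = 4k + 2Σᵢ<ⱼ c(rᵢⱼ) with c(r) = 3.263r + 0.710r² + 0.027r³; p from the moment-matched scaled χ² (scale = Var/2E, df = 2E²/Var) |
| stouffer | Z = Σzᵢ / √(1ᵀR1), zᵢ the upper-tail normal quantile of pᵢ |
| makambi | weighted Fisher M = Σwᵢ(−2 ln pᵢ) (equal weights by default), same scaled-χ² calibration with Var = 4Σwᵢ² + 2Σᵢ<ⱼ wᵢwⱼ c(rᵢⱼ) |
| method6 | decorrelated z-test: whiten z by R^(−1/2) (eigendecomposition, eigenvalues floored at 1e-8), refer Σ(whitened)/√k to N(0,1) |
| gates | effective number of tests mₑ = m − Σ_{λ>1}(λ − 1) over eigenvalues of the p-value correlation matrix, approximated by r²; p = min over j of mₑ p₍ⱼ₎ / mₑ(j) |
| ecs | T = Σ χ²₁-deviates; rescaled to Tₑ = T·mₑ/m and referred to χ² with mₑ df |

Design notes:

- The r² surrogate for the GATES/ECS p-value correlation (in place of the
  sixth-order polynomial of the original GATES derivation) is a monotone,
  self-contained approximation; it is exact at r ∈ {0, ±1}.
- The slot occupied by `method6` is a pluggable decorrelation test kept
  deliberately distinct from the other seven; the omnibus treats method
  columns generically, so rank-averaging is well defined whatever fills it.
- p-values are clipped to [1e-300, 1] before log/quantile transforms.
- Every statistic returns the SNP's own p for a single-SNP gene (checked to
  1e-10), and a pair duplicated at r = 1 collapses to the single-test p —
  for km_fisher exactly, because c(1) = 4.000 gives df = 2, scale = 2.
  *Appending* a duplicate to a gene that already has k ≥ 2 SNPs is **not**
  an invariant of the moment-matched approximations and is not claimed.
- Calibration: with two-sided input p-values the signed-r covariance
  polynomial overstates the dependence of the log/z transforms, so under
  strong LD (rho ≈ 0.8 blocks) km_fisher/stouffer/makambi/method6 are
  mildly conservative at the gene level. In the weak-LD regime (rho ≈ 0.3)
  all adjusted columns are uniform under the null (KS p > 0.01 in the test
  suite). The permutation omnibus recalibrates all eight columns regardless,
  which is why its empirical p — not the raw method p — carries the
  inference.

## Gene-set statistics

Sets are size-filtered *after* intersection with the annotation (15–300
genes inclusive, configurable). Each testable set receives:

- the six pooling statistics (minp … method6) on the deduplicated union of
  member genes' SNPs and its LD submatrix;
- a one-sided Wilcoxon rank-sum test that in-set genes have smaller
  gene-level GATES p-values than all other testable genes (exact enumeration
  when min(n_in, n_out) ≤ 10 and no ties; otherwise the tie- and
  continuity-corrected normal approximation — the permutation engine uses
  the normal path for observed and permuted tables alike so the two are
  computed identically);
- HYST: member genes sorted by GATES p are greedily pruned so retained genes
  are quasi-independent (max inter-gene SNP |r| < 0.5); retained GATES
  p-values are combined by the same scaled-χ² machinery with the pairwise
  max |r| as the inter-gene correlation summary. This key-gene selection and
  correlation summary are this package's concretization of the hybrid
  set-based test; an exactly duplicated gene is pruned and leaves the result
  unchanged.

q-values are computed separately within each input collection (and within
genes), mirroring per-category FDR control.

## Rank-averaging permutation omnibus

Within each method column, units are ranked ascending by p with midranks for
ties; the unit's score is its mean rank over the eight columns. The null is
built by Freedman–Lane permutation: the phenotype is residualized against
the covariates, residuals are permuted (one seeded sequence shared by all
units), the covariate fit is added back — equivalently, the permuted
residual vector is re-projected — and the entire chain (fast GWAS → gene
statistics → set statistics → rank average) is recomputed. Plain phenotype
shuffling would break the phenotype–covariate association and distort the
null. The empirical p uses the add-one estimator
(1 + #{avg_rank_b ≤ avg_rank_obs})/(B + 1), so it is never zero and its
floor 1/(B+1) mirrors reporting "< 1/B" at large B. Ranks are computed
within each (observed or permuted) table independently and only the average
ranks are compared across tables. Benjamini–Hochberg q-values (step-up with
cumulative-minimum monotonization) are computed per category; q < 0.1 is
flagged significant (strict inequality).

The per-permutation cost is dominated by the GATES prefix-eigenvalue scan;
a numba-compiled kernel (with an equivalent pure-numpy fallback, asserted
identical in the tests) brings one permutation of a 5000-SNP / 200-gene
problem to ≈ 45 ms on one core.

## Synthetic data

Genotypes: within each block of k SNPs, a latent Gaussian vector with AR(1)
correlation rho^|i−j| is thresholded at the normal quantile of each SNP's
MAF (drawn uniformly from `maf_range`); a dosage is the sum of two
independent haplotypes; blocks are independent and positions are laid out on
a regular bp grid with inter-block gaps. The genotype-scale r² is an
attenuated, monotone image of the latent rho (rho = 0.95 at common MAF gives
adjacent r² ≈ 0.5–0.6), which is the only property the clumping and
aggregation machinery relies on; no coalescent realism is attempted.
Defaults: 10 SNPs/block, rho = 0.8, MAF ∈ [0.05, 0.5], two recruitment
sites in the 773:985 proportion of the motivating design.

Phenotypes: score = intercept + Σ β·(standardized dosage) + covariate
effects + Gaussian noise, on a questionnaire-like scale (intercept 2.0, a
small site offset). Causal SNPs are placed strictly inside causal genes and
their betas are rescaled jointly so they explain exactly `h2_target` of the
phenotypic variance in expectation — making heritability bookkeeping exact.
Covariates: sex ~ Bernoulli(½), age ~ U(18, 60) with a small site shift, and
pc1..pc10 computed from the simulated genotypes by randomized SVD (so they
are genuine genetic PCs, deterministic given the seed). The brooding and
reflection noise terms share a latent component whose loading is *solved*
from the empirical variance of the fixed parts so the total correlation hits
the target (0.488 by default; achieved within sampling error ≈ 0.02 at
n = 1758). A single integer seed fans out to named substreams (genotypes /
phenotypes / annotation / truth) so each module is independently
reproducible. An optional missing-at-random knob exists; defaults are
complete-data.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: realistic MAF spectra and LD decay, population
stratification actually confounded with phenotype, genotyping error,
imputation uncertainty, non-Gaussian questionnaire noise, and real gene /
pathway structure. The studies validate the statistical machinery
(calibration, recovery, invariances), not field effect sizes.

## Reference studies and problem sizes

`generank.studies` fixes the package's standard experiments, shared by the
test suite and the acceptance script:

- **Null calibration**: 1000 individuals × 5000 SNPs, 200 genes (~10–20
  SNPs each after flanking), B = 500 permutations. Checks: λ within
  [0.95, 1.05]; fraction of genes with empirical p < 0.05 within 3
  Monte-Carlo SDs of 0.05; decile χ² goodness-of-fit p > 0.01.
- **Gene recovery**: 20 seeded replicates of 2000 individuals × 1000 SNPs,
  50 genes, one causal gene at h² = 0.03, B = 500; success = empirical
  p ≤ 0.01. Observed recovery ≈ 95%.
- **Set enrichment**: 2000 × 2000, 100 genes, three causal genes at total
  h² = 0.05 inside a 15-gene planted set versus 60 random null sets; the
  planted set's Wilcoxon p is compared against the null sets' (single
  seeded simulation, so the win fraction carries visible seed-to-seed
  variability).
- **Subscale correlation**: n = 1758, empirical brooding–reflection r vs
  the 0.488 target.

These sizes are desk-scale choices that keep each study to seconds–minutes
on a single core while leaving the Monte-Carlo error small relative to the
bands being checked.

## Numerical choices and edge cases

- Strict `<` for p-threshold filters and `≥` for r² removal in clumping;
  strict `<` for the q < 0.1 significance call.
- Eigenvalues floored at 1e-8 (whitening) and clipped at 0 for effective
  test counts; mₑ bounded to [1, m].
- Variance expressions in the scaled-χ² match must be positive; strongly
  negative correlation sums raise rather than return a bogus p.
- Collinear covariate designs fall back to the least-squares pseudo-inverse
  with a logged warning.
- Result tables serialize floats at 6 significant digits, p-values in
  scientific notation; writers are deterministic and write→read→write is
  byte-identical.

## Limitations

- The KGG-style ECS/GATES and HYST implementations are methodological
  re-derivations, not bit-for-bit ports of the reference software; the
  contract is the stated reduction, collapse and calibration properties.
- LD for aggregation is estimated from the analysis sample itself, not a
  reference panel.
- The omnibus currently permutes at the whole-sample level; site-stratified
  permutation is not implemented.
- Mixed models, logistic phenotypes, heritability estimation and external
  eQTL/chromatin annotation are out of scope.
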