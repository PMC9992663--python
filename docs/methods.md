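# Methods

## The problem

A transcriptome-wide association study (TWAS) tests whether the genetically
regulated component of a gene's expression (GReX) is associated with a
trait.  Classically this needs individual-level reference data to train a
per-gene model `e_g = X_g w + eps` of expression on cis-SNP genotypes.
This package instead trains the eQTL weight vector `w` from **summary-level
eQTL statistics** (per-SNP Z-scores, p-values, sample sizes) plus an LD
reference panel, by adapting four polygenic-score estimators, and then
tests each gene against GWAS summary statistics, combining the per-method
p-values with a Cauchy omnibus test.

## Stage I: weight estimation from summary statistics

All estimators consume the marginal standardized effects
`w~_j = Z_j / sqrt(median_j n_{g,j})` (the median cis-SNP sample size is
used throughout for robustness to meta-analytic sample-size variation) and
the reference LD matrix `R = X'X/n` of the standardized panel.  LD
clumping at r² > 0.99 is applied once as a common preprocessing step, and
the clumped window is partitioned into LD blocks by a greedy scan that
guarantees cross-block r² ≤ 0.1.

**P+T** — keep clump-index SNPs with marginal p ≤ P_T (0.001 and 0.05 are
run as two separate methods); weights are the marginal effects unchanged.
The threshold is boundary-inclusive.

**lassosum** — minimize
`(1−s)·w'R w + s·w'w − 2 w~'w + 2λ‖w‖₁`
by cyclic coordinate descent per block; with unit-diagonal LD the update
is an exact soft-threshold step.  The grid is s ∈ {0.2, 0.5, 0.9, 1} ×
20 log-spaced λ ∈ [1e-3, 1e-1], warm-started along the λ path, tuned per
gene by pseudovalidation `pv(w) = w'w~ / sqrt(w'Rw)` with ties toward
larger s then larger λ.  s = 1 is included as a positive-definite
fallback (pure soft-thresholding).

**SDPR-style Dirichlet-process regression** — a truncated normal-mixture
prior with an explicit point-mass null:
`w_j ~ π₀·δ₀ + Σ_k π_k·N(0, σ²_k · σ²_ε/n)`, stick-breaking π
(concentration α = 1, M = 20 slabs), inverse-gamma base (0.1, 0.1) on the
relative scales σ²_k.  The collapsed Gibbs sweep draws each SNP's
component with its effect integrated out, then the effect from its
conjugate normal, using only the sufficient statistics `n·w~` and `n·R`.

Two numerical choices matter here, both made after tracing chain
pathologies in the m ≈ n regime (cis windows can hold as many SNPs as the
reference has samples):

* slab variances are *relative* to the per-SNP sampling variance
  σ²_ε/n, so a shrinking residual variance tightens the prior instead of
  letting the fit interpolate;
* the residual variance is **fixed at 1 by default** (expression is
  standardized and per-SNP effects are small).  Sampling σ²_ε from the
  summary pseudo-likelihood is supported (`fix_sigma2_eps=None`) but at
  m ≈ n it is unstable: dense noise fits shrink σ²_ε, which raises the
  model's confidence κ = n/σ²_ε, which attracts further noise fits — a
  runaway that ends with the chain interpolating the marginal statistics.
  The chain also starts with null-heavy stick weights (π₀ = 0.9) so it
  begins in the sparse basin.

**PRS-CS-style continuous shrinkage** —
`w_j ~ N(0, (σ²_ε/n)·ψ_j)`, `ψ_j ~ Gamma(a, δ_j)`, `δ_j ~ Gamma(b, φ)`
with a = 1, b = 1/2: a sharp peak at zero with Cauchy-like tails.  The
global scale φ is fixed per run: 1e-4 for applications, and the square of
the causal proportion in simulation mode.  Gibbs steps: per-block
ridge-form MVN for w; generalized-inverse-Gaussian for ψ (for a = 1 the
order is exactly 1/2, sampled through the reciprocal inverse-Gaussian
identity with `Generator.wald`); gamma for δ; inverse-gamma for σ²_ε
under the scale-invariant Jeffreys prior 1/σ²_ε.  Local scales are capped
at ψ ≤ 1 (prior variance at most σ²_ε/n), the standard guard in this
sampler family.  Non-positive-definite blocks get a diagonal jitter
escalated ×10 up to three times.

Both samplers run 1000 iterations with 200 burn-in by default and return
posterior-mean weights; given a seed they are bit-reproducible.  Per-gene
seeds are derived from the master seed and a CRC of the gene identifier,
so multi-gene runs are independent of scheduling order.

## Stage II: gene-based tests and the omnibus

For the J SNPs with both a weight and a GWAS Z-score,

    Z_g = Σ_j ŵ_j Z_j / sqrt(ŵ' V ŵ)

with V the SNP correlation matrix (FUSION form) or covariance matrix with
per-SNP dosage SDs in the numerator (S-PrediXcan form); the two coincide
for standardized weights.  Genomic control rescales a set of gene Z
statistics so the median p equals 0.5 (λ_gc = median(z²)/0.45494; skipped
below 10 genes).  The omnibus p-value is the equal-weight ACAT
combination `0.5 − arctan(mean tan((0.5−p)π))/π`, with the tail form
1/(pπ) below 1e-15; methods with no test or an invalid model (test R²
≤ 0.01, strict) are excluded with the divisor reduced.  Significant genes
are pruned to an independent set greedily by ascending p, dropping genes
whose predicted-GReX squared correlation with a kept gene exceeds 0.5.

## Synthetic data

The generator emulates the evaluation design around the estimators:

* **Genotypes** — two haplotypes per sample from a latent Gaussian AR(1)
  chain (ρ = 0.9 between adjacent SNPs) thresholded at a per-SNP allele
  frequency drawn uniformly from [0.05, 0.5]; the chain restarts every 25
  SNPs (~100 kb at the 4 kb spacing), giving recombination-hotspot-style
  LD blocks with no cross-block correlation.  A smooth AR(1) decay admits
  no partition satisfying the hard cross-block rule, so blocky LD is both
  the more realistic and the computationally necessary default.  Default
  panel sizes are 568 training and 1326 test samples, m = 500 SNPs.
* **Expression** — `max(1, round(p_causal·m))` causal SNPs with N(0,1)
  effects rescaled so the causal variants explain exactly h_e² of the
  variance; noise N(0, 1−h_e²).  Study conditions: p_causal ∈
  {0.001, 0.01}, h_e² ∈ {0.01, 0.05, 0.1}.
* **eQTL summary statistics** — per-SNP OLS on the standardized training
  panel via the identity `w~_j = x_j'e/n`, with the t statistic treated
  as a normal Z.
* **GWAS Z-scores** — drawn directly from
  `Z ~ MVN(Σ_g w √(n_gwas·h_p²), Σ_g)` with Σ_g the test-panel SNP
  correlation matrix and h_p² = 0.025; n_gwas is matched to h_e²
  (500K / 100K / 40K for h_e² = 0.01 / 0.05 / 0.1 in the reported runs,
  the top of the ranges used per heritability level).

What the generator does **not** emulate: allele-frequency-dependent LD,
long-range LD and population structure, meta-analytic heterogeneity in
per-SNP sample sizes, and non-Gaussian expression noise.  Passing tests
therefore demonstrate correctness of the estimators and calibration of
the tests under idealized LD, not performance on real cohorts.

## Evaluation protocols and problem sizes

* **Power** — per scenario, 10 expression replicates × 20 GWAS Z-score
  draws (200 TWAS tests) at m = 500, counted at the genome-wide threshold
  2.5e-6 (0.05 / 20K genes).  The omnibus combines all five method
  p-values in simulation; the validity filter is the application-mode
  protocol.
* **Type-I error** — 20 trained genes × 5000 permuted-weight null tests
  (1e5 total): null Z ~ MVN(0, Σ_g), weight-to-SNP assignment permuted
  per test (one permutation shared across methods).
* **Recovery** — 50 replicates with one causal SNP (h_e² = 0.1,
  n_train = 2000); success is the causal SNP carrying the largest
  absolute weight.
* The bulk stochastic suites run the samplers at 500 iterations / 125
  burn-in, a scaled-down setting chosen once for the package's replicate
  counts; oracle checks use the 1000/200 defaults or longer.

## Known limitations

* lassosum's pseudovalidation statistic prefers dense low-λ solutions on
  noisy summary data; its selected models are the weakest of the four in
  low-heritability scenarios (consistent with its relative ordering in
  published comparisons).
* The omnibus p-value is slightly anti-conservative at modest
  significance levels (a known property of Cauchy combination under
  strong dependence); it is calibrated in the stringent tail used for
  discovery, and the test suite checks exactly that.
* Sampling σ²_ε in the DP sampler is unreliable for m ≳ n (see above);
  the default avoids it.
* The PLINK reader/writer covers the SNP-major bed/bim/fam triplet only;
  multi-allelic sites should be split or dropped upstream (the harmonizer
  drops non-matching alleles and counts them).
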