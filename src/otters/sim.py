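"""Synthetic data generation and evaluation metrics for the TWAS pipeline.

The generator emulates the study design used to benchmark summary-level
TWAS training: correlated diploid genotypes for a training panel (the
expression reference, default n=568) and a test panel (the GWAS/LD side,
default n=1326); gene expression from ``e = X w + eps`` with a chosen
causal proportion ``p_causal`` and expression heritability ``h_e2``
(effects rescaled so the causal variants explain exactly ``h_e2`` of the
variance); single-SNP eQTL summary statistics computed from the training
panel; and GWAS Z-scores drawn directly from

    Z ~ MVN(Sigma_g w sqrt(n_gwas h_p2), Sigma_g),

where ``Sigma_g`` is the test-panel SNP correlation matrix and ``h_p2``
(default 0.025) the phenotypic variance explained by GReX.

Genotypes come from a latent AR(1) Gaussian haplotype model thresholded at
each SNP's allele frequency — a stand-in for real whole-genome-sequencing
panels that gives controllable, monotonically decaying LD.  What it does
not emulate: allele-frequency/LD coupling, long-range LD, and population
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ldpanel import GenotypePanel

#: genomic spacing (bp) between adjacent simulated SNPs
_SNP_SPACING = 4000


@dataclass
class SimConfig:
    n_train: int = 568
    n_test: int = 1326
    m_snps: int = 500
    ld_rho: float = 0.9          # latent AR(1) haplotype correlation
    ld_block_size: int = 25      # AR(1) chain restarts every this many SNPs
    maf_range: tuple = (0.05, 0.5)
    p_causal: float = 0.001
    h_e2: float = 0.1
    h_p2: float = 0.025
    n_gwas: int = 10_000
    seed: int = 0
    chrom: str = "1"
    tss: int = 1_000_000         # nominal transcription start site

    def __post_init__(self) -> None:
        if not 0 <= self.h_e2 < 1:
            raise ValueError("h_e2 must be in [0, 1)")
        if not 0 <= self.h_p2 < 1:
            raise ValueError("h_p2 must be in [0, 1)")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")

    @property
    def n_causal(self) -> int:
        return max(1, round(self.p_causal * self.m_snps))


@dataclass
class SimTruth:
    """Ground truth of one simulated gene."""

    causal_indices: np.ndarray
    w_true: np.ndarray           # standardized-scale effects, zeros off-causal
    expression: np.ndarray       # per-sample e_g (training first, then test)


def _haplotypes(n: int, m: int, rho: float, block: int, thresholds: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """One allele per (sample, SNP) from a thresholded latent AR(1) process.

    The latent chain restarts at every ``block`` boundary, giving
    recombination-hotspot-style LD blocks with no cross-block correlation.
    """
    latent = np.empty((n, m))
    innov = rng.standard_normal((n, m))
    scale = np.sqrt(1.0 - rho ** 2)
    latent[:, 0] = innov[:, 0]
    for j in range(1, m):
        if block > 0 and j % block == 0:
            latent[:, j] = innov[:, j]
        else:
            latent[:, j] = rho * latent[:, j - 1] + scale * innov[:, j]
    return (latent < thresholds).astype(np.float64)


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None):
    """Simulate training and test genotype panels sharing MAFs and LD.

    Returns ``(train_panel, test_panel)``; dosages are ALT-allele counts
    summed over two independent haplotypes.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = config.m_snps
    maf = rng.uniform(*config.maf_range, size=m)
    thresh = stats.norm.ppf(maf)
    variants = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": config.tss + _SNP_SPACING * (np.arange(m) - m // 2),
            "ref": "A",
            "alt": "G",
        }
    )
    panels = []
    for n in (config.n_train, config.n_test):
        dosage = (
            _haplotypes(n, m, config.ld_rho, config.ld_block_size, thresh, rng)
            + _haplotypes(n, m, config.ld_rho, config.ld_block_size, thresh, rng)
        )
        panels.append(GenotypePanel(dosages=dosage, variants=variants.copy(),
                                    samples=[f"S{i+1}" for i in range(n)]))
    return panels[0], panels[1]


def simulate_expression(X_std: np.ndarray, config: SimConfig,
                        rng: np.random.Generator | None = None) -> SimTruth:
    """Simulate expression ``e = X w + eps`` on a standardized genotype matrix.

    ``max(1, round(p_causal * m))`` causal SNPs get N(0,1) effects rescaled
    so the empirical variance of ``X w`` equals ``h_e2`` exactly;
    ``eps ~ N(0, 1 - h_e2)``.  With ``h_e2 = 0`` the effects are all zero.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = X_std.shape
    causal = np.sort(rng.choice(m, size=config.n_causal, replace=False))
    w = np.zeros(m)
    if config.h_e2 > 0:
        raw = rng.standard_normal(config.n_causal)
        while np.allclose(X_std[:, causal] @ raw, 0):  # pragma: no cover
            raw = rng.standard_normal(config.n_causal)
        g = X_std[:, causal] @ raw
        raw *= np.sqrt(config.h_e2 / g.var())
        w[causal] = raw
    e = X_std @ w + rng.normal(0.0, np.sqrt(1.0 - config.h_e2), size=n)
    return SimTruth(causal_indices=causal, w_true=w, expression=e)


def eqtl_sumstats_from_individual(X_std: np.ndarray, e: np.ndarray) -> pd.DataFrame:
    """Single-SNP OLS summary statistics from individual-level data.

    For standardized genotype columns the marginal effect is
    ``w_tilde_j = x_j' e / n``; the OLS t statistic is treated as a normal
    Z-score with a two-sided p-value.  Returns a frame with columns
    ``beta_marginal, z, p, n``.
    """
    X = np.asarray(X_std, dtype=float)
    e = np.asarray(e, dtype=float)
    e = (e - e.mean()) / e.std()  # marginal identity assumes standardized e
    n = X.shape[0]
    bhat = X.T @ e / n
    rss = e @ e - n * bhat ** 2  # residual SS per SNP (x'x = n)
    dof = n - 2
    se = np.sqrt(np.maximum(rss, 0.0) / dof / n)
    with np.errstate(divide="ignore"):
        z = np.where(se > 0, bhat / se, np.inf * np.sign(bhat))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"beta_marginal": bhat, "z": z,
                         "p": np.clip(p, 1e-300, 1.0), "n": n})


def simulate_gwas_z(w_true: np.ndarray, Sigma: np.ndarray, config: SimConfig,
                    rng: np.random.Generator | None = None, size: int = 1,
                    jitter: float = 1e-6) -> np.ndarray:
    """Draw GWAS Z-score vectors from MVN(Sigma w sqrt(n_gwas h_p2), Sigma).

    Returns an array of shape ``(size, m)``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    Sigma = np.asarray(Sigma, dtype=float)
    m = Sigma.shape[0]
    mean = Sigma @ np.asarray(w_true, dtype=float) * np.sqrt(config.n_gwas * config.h_p2)
    eps = 0.0
    while True:
        try:
            L = np.linalg.cholesky(Sigma + eps * np.eye(m))
            break
        except np.linalg.LinAlgError:
            eps = jitter if eps == 0.0 else eps * 10.0
    return mean + rng.standard_normal((size, m)) @ L.T


def test_r2(grex: np.ndarray, expression: np.ndarray) -> float:
    """Squared Pearson correlation between imputed GReX and expression.

    Returns 0.0 when either vector is constant (undefined correlation).
    """
    a = np.asarray(grex, dtype=float)
    b = np.asarray(expression, dtype=float)
    if a.shape != b.shape:
        raise ValueError("grex and expression must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def power_and_type1(p_values, threshold: float) -> float:
    """Fraction of p-values below the significance threshold.

    ``None``/NaN entries (no-test genes) count as non-rejections.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    p = np.array([np.nan if q is None else q for q in np.atleast_1d(p_values)], dtype=float)
    if p.size == 0:
        return 0.0
    return float(np.mean(p < threshold))


def permuted_weight_null(weights: np.ndarray, rng: np.random.Generator,
                         size: int = 1) -> np.ndarray:
    """Permute the weight-to-SNP assignment (null-calibration protocol).

    Returns ``(size, m)`` permuted copies of the weight vector.
    """
    w = np.asarray(weights, dtype=float)
    idx = np.argsort(rng.random((size, w.size)), axis=1)
    return w[idx]
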