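"""Stage-II TWAS: GReX imputation, gene-based Z tests, genomic control,
Cauchy omnibus combination, and result filtering.

With trained eQTL weights ``w_hat`` and GWAS single-SNP Z-scores ``z``, the
gene-based burden-style statistic over the J SNPs carrying both a weight
and a Z-score is

    Z_g = sum_j w_hat_j z_j / sqrt(w_hat' V w_hat),

where V is the SNP correlation matrix (FUSION form) or covariance matrix
(S-PrediXcan form, which additionally multiplies each z_j by the SNP's
dosage standard deviation sigma_j).  For weights on the standardized
scale and unit sigma_j the two forms coincide.

Per-method p-values for one gene are combined with the aggregated Cauchy
test (ACAT-O): T = mean_i tan((0.5 - p_i) * pi), omnibus p = 0.5 -
arctan(T)/pi, using the tail approximation tan((0.5-p)pi) ~ 1/(p*pi) for
tiny p.  Genomic control rescales a set of gene-level Z statistics so the
median p equals 0.5 (chi^2_1 median 0.45494).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

CHI2_1_MEDIAN = 0.45494  # median of chi-square with 1 df (4-decimal constant)
_P_CLIP = 1e-15
_DENOM_FLOOR = 1e-12


@dataclass
class TWASResult:
    """Per-gene association results across training methods."""

    gene_id: str
    method_z: dict = field(default_factory=dict)    # method -> Z_g (or None)
    method_p: dict = field(default_factory=dict)    # method -> p (or None)
    n_snps_used: dict = field(default_factory=dict)
    valid_model: dict = field(default_factory=dict)  # method -> bool
    otters_p: float | None = None
    independent: bool = True


def impute_grex(X_std: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Genetically regulated expression ``GReX = X_new w_hat``."""
    return np.asarray(X_std) @ np.asarray(weights, dtype=float)


def twas_z(weights: np.ndarray, z: np.ndarray, V: np.ndarray,
           form: str = "fusion", snp_sd: np.ndarray | None = None):
    """Gene-based Z statistic and two-sided p from GWAS summary Z-scores.

    Parameters
    ----------
    weights, z : aligned weight and GWAS Z vectors over the J shared SNPs.
    V : SNP correlation (FUSION) or covariance (S-PrediXcan) matrix.
    form : "fusion" or "spredixcan".
    snp_sd : per-SNP dosage standard deviations (S-PrediXcan numerator).

    Returns ``(Z_g, p)`` or ``None`` when no SNP is testable or the
    denominator underflows (no-test signal).
    """
    w = np.asarray(weights, dtype=float)
    z = np.asarray(z, dtype=float)
    if w.size == 0:
        return None
    denom2 = float(w @ np.asarray(V) @ w)
    if denom2 <= _DENOM_FLOOR:
        return None
    form = form.lower()
    if form == "fusion":
        num = float(w @ z)
    elif form == "spredixcan":
        sd = np.ones_like(w) if snp_sd is None else np.asarray(snp_sd, dtype=float)
        num = float(w @ (sd * z))
    else:
        raise ValueError(f"unknown test form {form!r}")
    zg = num / math.sqrt(denom2)
    return zg, z_to_p(zg)


def z_to_p(z) -> np.ndarray | float:
    """Two-sided normal-tail p-value."""
    return 2.0 * stats.norm.sf(np.abs(z))


def genomic_control(z_values: np.ndarray):
    """Rescale gene-level Z statistics so the median p equals 0.5.

    Returns ``(adjusted_p, lambda_gc)`` with
    ``lambda_gc = median(z^2) / 0.45494``.  With fewer than 10 genes the
    correction is skipped (lambda = 1) with a warning.
    """
    z = np.asarray(z_values, dtype=float)
    if z.size < 10:
        warnings.warn("fewer than 10 genes: genomic control skipped", stacklevel=2)
        return z_to_p(z), 1.0
    lam = float(np.median(z ** 2) / CHI2_1_MEDIAN)
    return z_to_p(z / math.sqrt(lam)), lam


def acat_o(p_values, weights=None) -> float | None:
    """Aggregated Cauchy omnibus p-value.

    Non-finite entries are ignored; an empty input returns ``None``
    (no-test signal).  Equal weights by default.
    """
    p = np.asarray([q for q in np.atleast_1d(p_values) if q is not None and np.isfinite(q)],
                   dtype=float)
    if p.size == 0:
        return None
    if weights is None:
        wts = np.full(p.size, 1.0 / p.size)
    else:
        wts = np.asarray(weights, dtype=float)
        wts = wts / wts.sum()
    small = p < _P_CLIP
    clipped = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    terms = np.tan((0.5 - clipped) * np.pi)
    # tail-stable form tan((0.5-p)*pi) ~ 1/(p*pi) for extreme p
    terms[small] = 1.0 / (np.maximum(p[small], 1e-300) * np.pi)
    T = float(wts @ terms)
    if T > 1e15:  # arctan saturates in double precision
        return 1.0 / (T * np.pi)
    return 0.5 - math.atan(T) / math.pi


def filter_valid(test_r2, threshold: float = 0.01):
    """Valid-model flag: out-of-sample R^2 strictly above the threshold."""
    return np.asarray(test_r2, dtype=float) > threshold


def prune_independent(grex_matrix: np.ndarray, p_values: np.ndarray,
                      r2_cut: float = 0.5) -> np.ndarray:
    """Greedy pruning of correlated genes: indices of retained (independent) genes.

    Genes are visited by ascending TWAS p (ties by column order); each kept
    gene removes all remaining genes whose squared Pearson correlation of
    predicted GReX with it exceeds ``r2_cut``.
    """
    G = np.asarray(grex_matrix, dtype=float)
    p = np.asarray(p_values, dtype=float)
    k = G.shape[1]
    with np.errstate(invalid="ignore"):
        corr2 = np.corrcoef(G, rowvar=False) ** 2
    corr2 = np.nan_to_num(np.atleast_2d(corr2), nan=0.0)
    order = np.lexsort((np.arange(k), p))
    alive = np.ones(k, dtype=bool)
    kept = []
    for j in order:
        if not alive[j]:
            continue
        kept.append(j)
        alive &= ~(corr2[j] > r2_cut)
        alive[j] = False
    return np.array(sorted(kept), dtype=int)


def bonferroni(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
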