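"""Per-gene orchestration: Stage-I training across methods, Stage-II tests,
and the simulation experiments (power, type-I error, parameter recovery).

All randomness is controlled by a master seed; per-gene / per-replicate
seeds are derived deterministically from it and a stable hash of the gene
identifier, so results are independent of scheduling order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as _st

from .lassosum import LassosumConfig, fit_lassosum
from .ldpanel import LDStructure, compute_ld, ld_clump, partition_blocks, standardize
from .prscs import PRSCSConfig, fit_prscs
from .pt import PTConfig, fit_pt
from .sdpr import SDPRConfig, fit_sdpr
from .sim import (
    SimConfig,
    eqtl_sumstats_from_individual,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas_z,
    test_r2,
)
from .twas import acat_o, filter_valid, twas_z

#: canonical method order (two P+T thresholds count as two methods)
METHODS = ("PT_0.001", "PT_0.05", "lassosum", "SDPR", "PRScs")

GENOME_WIDE_ALPHA = 2.5e-6  # 0.05 / 20K independent genes


def derive_seed(master_seed: int, *tokens) -> int:
    """Deterministic sub-seed below 2**31 from a master seed and labels."""
    h = zlib.crc32(("|".join(str(t) for t in tokens)).encode())
    return int(np.random.SeedSequence([master_seed, h]).generate_state(1)[0] % (2 ** 31))


@dataclass
class TrainConfig:
    """Stage-I settings shared across methods for one run."""

    r2_clump: float = 0.99
    r2_block: float = 0.1
    pt_thresholds: tuple = (0.001, 0.05)
    lassosum: LassosumConfig = field(default_factory=LassosumConfig)
    phi: float = 1e-4
    mcmc_iters: int = 1000
    mcmc_burnin: int = 200
    methods: tuple = METHODS


def train_gene(betas, p_values, R_full, n_median: int, seed: int,
               config: TrainConfig = None) -> dict:
    """Train eQTL weights for one gene with every requested method.

    LD clumping at ``r2_clump`` is applied once as a common preprocessing
    step; the clumped window is then re-partitioned into LD blocks for the
    block solvers.  Returns dense weight vectors over the input SNP order
    (zeros for removed/unselected SNPs), keyed by method name.
    """
    if config is None:
        config = TrainConfig()
    betas = np.asarray(betas, dtype=float)
    p_values = np.asarray(p_values, dtype=float)
    m = betas.size
    out = {meth: np.zeros(m) for meth in config.methods}
    if m == 0:
        return out

    kept = ld_clump(p_values, R_full, config.r2_clump)
    sub_R = np.asarray(R_full)[np.ix_(kept, kept)]
    blocks = partition_blocks(sub_R, config.r2_block)
    ld = LDStructure(R=sub_R, blocks=blocks)
    b_sub, p_sub = betas[kept], p_values[kept]

    for i, pt in enumerate(config.pt_thresholds):
        name = f"PT_{pt:g}"
        if name in out:
            out[name][kept] = fit_pt(b_sub, p_sub, ld, PTConfig(p_threshold=pt))
    if "lassosum" in out:
        w, _ = fit_lassosum(b_sub, ld, config.lassosum)
        out["lassosum"][kept] = w
    if "SDPR" in out:
        cfg = SDPRConfig(iters=config.mcmc_iters, burnin=config.mcmc_burnin,
                         seed=derive_seed(seed, "SDPR"))
        w, _ = fit_sdpr(b_sub, n_median, ld, cfg)
        out["SDPR"][kept] = w
    if "PRScs" in out:
        cfg = PRSCSConfig(phi=config.phi, iters=config.mcmc_iters,
                          burnin=config.mcmc_burnin, seed=derive_seed(seed, "PRScs"))
        w, _ = fit_prscs(b_sub, n_median, ld, cfg)
        out["PRScs"][kept] = w
    return out


def otters_p_value(method_p: dict, valid: dict) -> float | None:
    """ACAT-O combination over methods with a valid model and a test p."""
    ps = [p for meth, p in method_p.items()
          if p is not None and valid.get(meth, True)]
    return acat_o(ps) if ps else None


# ---------------------------------------------------------------------------
# simulation experiments
# ---------------------------------------------------------------------------

@dataclass
class GeneReplicate:
    """One trained simulation replicate, ready for repeated Stage-II tests."""

    weights: dict             # method -> dense weight vector
    valid: dict               # method -> bool (test R^2 > 0.01)
    test_r2: dict             # method -> float
    w_true: np.ndarray
    causal_indices: np.ndarray
    Sigma_test: np.ndarray    # test-panel SNP correlation (V and GWAS LD)


def simulate_and_train(cfg: SimConfig, train_cfg: TrainConfig = None) -> GeneReplicate:
    """Simulate one gene (genotypes, expression, eQTL summary data) and train.

    The eQTL summary statistics come from the training panel; the
    reference LD used by the estimators is the training-panel LD; the
    test-panel correlation matrix doubles as the Stage-II ``V`` and the
    GWAS Z-score covariance.
    """
    if train_cfg is None:
        train_cfg = TrainConfig(phi=cfg.p_causal ** 2)
    rng = np.random.default_rng(cfg.seed)
    train, test = simulate_genotypes(cfg, rng)
    X_tr, kept_tr, _ = standardize(train)
    X_te, kept_te, _ = standardize(test)
    if len(kept_tr) != cfg.m_snps or len(kept_te) != cfg.m_snps:
        # rare monomorphic drop: keep only SNPs polymorphic in both panels
        common = np.intersect1d(kept_tr, kept_te)
        X_tr = X_tr[:, np.searchsorted(kept_tr, common)]
        X_te = X_te[:, np.searchsorted(kept_te, common)]
    truth = simulate_expression(np.vstack([X_tr, X_te]), cfg, rng)
    e_tr = truth.expression[: cfg.n_train]
    e_te = truth.expression[cfg.n_train:]

    ss = eqtl_sumstats_from_individual(X_tr, e_tr)
    R_train = compute_ld(X_tr).R
    Sigma_test = compute_ld(X_te).R
    weights = train_gene(ss["beta_marginal"].values, ss["p"].values, R_train,
                         cfg.n_train, derive_seed(cfg.seed, "train"), train_cfg)
    r2 = {meth: test_r2(X_te @ w, e_te) if np.any(w) else 0.0
          for meth, w in weights.items()}
    valid = {meth: bool(filter_valid(v)) for meth, v in r2.items()}
    return GeneReplicate(weights=weights, valid=valid, test_r2=r2,
                         w_true=truth.w_true, causal_indices=truth.causal_indices,
                         Sigma_test=Sigma_test)


def run_power_scenario(cfg: SimConfig, n_expr_reps: int = 10, n_zsets: int = 20,
                       threshold: float = GENOME_WIDE_ALPHA,
                       train_cfg: TrainConfig = None, require_valid: bool = False):
    """TWAS power per method (and omnibus) for one simulation scenario.

    ``n_expr_reps`` expression replicates are simulated and trained; each
    is tested against ``n_zsets`` independent GWAS Z-score draws.  Power is
    the fraction of the ``n_expr_reps * n_zsets`` tests with p below the
    genome-wide threshold; no-test genes count as non-rejections.  With
    ``require_valid`` the omnibus test combines only methods whose model
    passed the test-R^2 validity filter (the real-data protocol); by
    default all available method p-values are combined.

    Returns ``(power, mean_test_r2)`` dicts keyed by method plus "OTTERS".
    """
    hits = {meth: 0 for meth in METHODS}
    hits["OTTERS"] = 0
    r2_sum = {meth: 0.0 for meth in METHODS}
    total = 0
    for rep in range(n_expr_reps):
        rep_cfg = replace(cfg, seed=derive_seed(cfg.seed, "rep", rep))
        gene = simulate_and_train(rep_cfg, train_cfg)
        valid = gene.valid if require_valid else {meth: True for meth in METHODS}
        for meth in METHODS:
            r2_sum[meth] += gene.test_r2[meth]
        z_rng = np.random.default_rng(derive_seed(cfg.seed, "zset", rep))
        Z = simulate_gwas_z(gene.w_true, gene.Sigma_test, rep_cfg, z_rng, size=n_zsets)
        for b in range(n_zsets):
            method_p = {}
            for meth in METHODS:
                res = twas_z(gene.weights[meth], Z[b], gene.Sigma_test)
                method_p[meth] = None if res is None else res[1]
                if method_p[meth] is not None and method_p[meth] < threshold:
                    hits[meth] += 1
            po = otters_p_value(method_p, valid)
            if po is not None and po < threshold:
                hits["OTTERS"] += 1
            total += 1
    power = {k: v / total for k, v in hits.items()}
    mean_r2 = {k: v / n_expr_reps for k, v in r2_sum.items()}
    return power, mean_r2


def run_type1(cfg: SimConfig, n_genes: int = 20, n_null_per_gene: int = 5000,
              train_cfg: TrainConfig = None) -> dict:
    """Null p-values under the permuted-weight protocol.

    For each trained gene, null GWAS Z-scores are drawn from
    ``MVN(0, Sigma_test)`` and the weight-to-SNP assignment is permuted
    (one permutation per test, shared across methods).  Returns p-value
    arrays keyed by method plus "OTTERS".
    """
    pvals: dict = {meth: [] for meth in METHODS}
    pvals["OTTERS"] = []
    for g in range(n_genes):
        g_cfg = replace(cfg, seed=derive_seed(cfg.seed, "t1gene", g))
        gene = simulate_and_train(g_cfg, train_cfg)
        rng = np.random.default_rng(derive_seed(cfg.seed, "t1null", g))
        m = gene.w_true.size
        Z = rng.standard_normal((n_null_per_gene, m)) @ \
            np.linalg.cholesky(gene.Sigma_test + 1e-6 * np.eye(m)).T
        perm = np.argsort(rng.random((n_null_per_gene, m)), axis=1)
        Sig = gene.Sigma_test
        per_method_p = {}
        for meth in METHODS:
            W = gene.weights[meth][perm]  # (B, m) permuted weights
            num = np.einsum("bm,bm->b", W, Z)
            den2 = np.einsum("bm,bm->b", W @ Sig, W)
            ok = den2 > 1e-12
            p = np.full(n_null_per_gene, np.nan)
            p[ok] = 2.0 * _st.norm.sf(np.abs(num[ok] / np.sqrt(den2[ok])))
            per_method_p[meth] = p
            pvals[meth].append(p)
        for b in range(n_null_per_gene):
            mp = {meth: (None if np.isnan(per_method_p[meth][b]) else per_method_p[meth][b])
                  for meth in METHODS}
            pvals["OTTERS"].append(otters_p_value(mp, gene.valid))
    out = {meth: np.concatenate(v) for meth, v in pvals.items() if meth != "OTTERS"}
    out["OTTERS"] = np.array([np.nan if p is None else p for p in pvals["OTTERS"]])
    return out


def run_recovery(cfg: SimConfig, n_reps: int = 50, train_cfg: TrainConfig = None,
                 methods=("SDPR", "PRScs")) -> dict:
    """Causal-SNP identification rate for the Bayesian estimators.

    For each replicate (single causal SNP), success means the causal SNP
    carries the largest absolute trained weight for the method.  Returns
    per-method rates and the joint rate.
    """
    wins = {meth: 0 for meth in methods}
    joint = 0
    for rep in range(n_reps):
        rep_cfg = replace(cfg, seed=derive_seed(cfg.seed, "recov", rep))
        gene = simulate_and_train(rep_cfg, train_cfg)
        causal = gene.causal_indices[0]
        ok_all = True
        for meth in methods:
            ok = np.argmax(np.abs(gene.weights[meth])) == causal
            wins[meth] += ok
            ok_all &= ok
        joint += ok_all
    out = {meth: wins[meth] / n_reps for meth in methods}
    out["joint"] = joint / n_reps
    return out
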