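"""Bayesian continuous-shrinkage regression (PRS-CS-style).

Effect sizes get the gamma-gamma scale-mixture prior

    w_j ~ N(0, (sigma2_eps / n) * psi_j),
    psi_j ~ Gamma(a, delta_j),   delta_j ~ Gamma(b, phi),

with a = 1 and b = 1/2 by default, which puts a sharp peak at zero (to
shrink small, likely-null effects) and Cauchy-like tails (to leave large
effects essentially untouched).  ``phi`` is the fixed global-shrinkage
parameter acting through the rate of delta: 1e-4 is the application
default, and in simulation mode it is set to the square of the causal-SNP
proportion.  The residual variance carries the scale-invariant Jeffreys
prior p(sigma2_eps) ∝ 1/sigma2_eps.

Gibbs sampling uses only the summary statistics w_tilde and the reference
LD blocks: per block, w | psi has the ridge-form conditional
N((R + Psi^-1)^-1 w_tilde, (sigma2_eps/n)(R + Psi^-1)^-1) with
Psi = diag(psi_j); local scales follow a generalized inverse-Gaussian
conditional (sampled through the inverse-Gaussian reciprocal identity when
the GIG order is 1/2, i.e. whenever a = 1) and are capped at 1 so no SNP's
prior variance exceeds sigma2_eps/n.  Weights returned are posterior means
over post-burn-in draws; runs are bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ldpanel import LDStructure

_SS_FLOOR = 1e-8


@dataclass
class PRSCSConfig:
    a: float = 1.0
    b: float = 0.5
    phi: float = 1e-4
    iters: int = 1000
    burnin: int = 200
    seed: int = 0
    jitter: float = 1e-3
    fix_psi: tuple | None = None  # freeze local scales (ridge-oracle hook)

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.phi <= 0:
            raise ValueError("a, b and phi must be positive")
        if self.burnin >= self.iters:
            raise ValueError("burnin must be < iters")


@dataclass
class ShrinkageState:
    """Trace of the shrinkage parameters over recorded iterations."""

    psi: np.ndarray         # (n_kept, m) local scales
    delta: np.ndarray       # (n_kept, m)
    sigma2_eps: np.ndarray  # (n_kept,)


def sample_gig_half(a_par: np.ndarray, b_par: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from GIG(1/2, a, b): density ∝ x^{-1/2} exp(-(a x + b/x)/2).

    Uses 1/X ~ InverseGaussian(mu=sqrt(a/b), lambda=a); for b ≈ 0 the
    distribution degenerates to Gamma(1/2, rate a/2).
    """
    a_par = np.asarray(a_par, dtype=float)
    b_par = np.asarray(b_par, dtype=float)
    out = np.empty(np.broadcast(a_par, b_par).shape)
    a_par, b_par = np.broadcast_arrays(a_par, b_par)
    tiny = b_par < 1e-14
    if np.any(~tiny):
        mu = np.sqrt(a_par[~tiny] / b_par[~tiny])
        y = rng.wald(mu, a_par[~tiny])
        out[~tiny] = 1.0 / y
    if np.any(tiny):
        out[tiny] = rng.gamma(0.5, 2.0 / a_par[tiny])
    return out


def _chol_with_jitter(A: np.ndarray, jitter: float, tries: int = 3) -> np.ndarray:
    """Cholesky factor of A, escalating a diagonal jitter x10 up to `tries` times."""
    eps = 0.0
    for t in range(tries + 1):
        try:
            return np.linalg.cholesky(A + eps * np.eye(A.shape[0]))
        except np.linalg.LinAlgError:
            eps = jitter * (10.0 ** t)
    raise np.linalg.LinAlgError("block not positive definite after jitter escalation")


def fit_prscs(betas: np.ndarray, n: int, ld: LDStructure,
              config: PRSCSConfig = None):
    """Posterior-mean eQTL weights under the continuous-shrinkage prior.

    Returns ``(w_hat, state)`` with a :class:`ShrinkageState` trace of the
    recorded iterations.
    """
    if config is None:
        config = PRSCSConfig()
    betas = np.asarray(betas, dtype=float)
    m = betas.size
    rng = np.random.default_rng(config.seed)

    psi = np.ones(m) if config.fix_psi is None \
        else np.asarray(config.fix_psi, dtype=float).copy()
    delta = np.ones(m)
    sigma2_eps = 1.0
    w = np.zeros(m)

    blocks = [(a, b, np.ascontiguousarray(R)) for a, b, R in ld.block_matrices()]
    kept_w, kept_psi, kept_delta, kept_s2 = [], [], [], []

    for it in range(config.iters):
        # (i) effect sizes, block-wise ridge-form conditional
        for a0, b0, Rb in blocks:
            A = Rb + np.diag(1.0 / psi[a0:b0])
            L = _chol_with_jitter(A, config.jitter)
            mean = np.linalg.solve(L.T, np.linalg.solve(L, betas[a0:b0]))
            z = rng.standard_normal(b0 - a0)
            w[a0:b0] = mean + np.sqrt(sigma2_eps / n) * np.linalg.solve(L.T, z)

        # (ii-iii) local shrinkage and its gamma mixing variable
        if config.fix_psi is None:
            b_par = n * w ** 2 / sigma2_eps
            if config.a == 1.0:
                psi = sample_gig_half(2.0 * delta, b_par, rng)
            else:  # general GIG order a - 1/2
                p_ord = config.a - 0.5
                omega = np.sqrt(np.clip(2.0 * delta * b_par, 1e-300, None))
                scale = np.sqrt(b_par / (2.0 * delta))
                psi = stats.geninvgauss.rvs(p_ord, omega, scale=scale, random_state=rng)
            # cap the per-SNP prior variance at sigma2_eps/n (psi <= 1),
            # the standard numerical guard for this sampler family
            psi = np.clip(psi, 1e-12, 1.0)
            delta = rng.gamma(config.a + config.b, 1.0 / (psi + config.phi))
            delta = np.clip(delta, 1e-12, None)

        # (iv) residual variance, Jeffreys prior 1/sigma2
        quad = sum(w[a0:b0] @ Rb @ w[a0:b0] for a0, b0, Rb in blocks)
        fit_ss = max(1.0 - 2.0 * betas @ w + quad, _SS_FLOOR)
        prior_ss = np.sum(w ** 2 / psi)  # w' Psi^-1 w
        shape = (n + m) / 2.0
        scale = 0.5 * n * (fit_ss + prior_ss)
        sigma2_eps = float(np.clip(scale / rng.gamma(shape), 1e-8, 1e3))

        if it >= config.burnin:
            kept_w.append(w.copy())
            kept_psi.append(psi.copy())
            kept_delta.append(delta.copy())
            kept_s2.append(sigma2_eps)

    state = ShrinkageState(
        psi=np.array(kept_psi), delta=np.array(kept_delta), sigma2_eps=np.array(kept_s2)
    )
    return np.mean(kept_w, axis=0), state
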