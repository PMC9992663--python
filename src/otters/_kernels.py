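"""Numba-compiled inner loops for the block solvers.

Coordinate-descent (lassosum) and collapsed Gibbs (Dirichlet-process
regression) sweeps are inherently sequential over SNPs, so the hot loops
are compiled.  Kernels are deterministic given their inputs; all
randomness enters through pre-drawn uniform/normal arrays so the callers
keep full control of seeding.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lassosum_cd_block(Rb, bb, wb, one_minus_s, lam, max_iter, tol):
    """Cyclic coordinate descent on one LD block.

    Minimizes (1-s) w'Rb w + s w'w - 2 bb'w + 2 lam |w|_1 in place
    (unit-diagonal Rb).  Returns 1 if converged within max_iter sweeps.
    """
    p = wb.shape[0]
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            acc = 0.0
            for k in range(p):
                if k != j:
                    acc += Rb[j, k] * wb[k]
            x = bb[j] - one_minus_s * acc
            if x > lam:
                new = x - lam
            elif x < -lam:
                new = x + lam
            else:
                new = 0.0
            d = abs(new - wb[j])
            if d > delta:
                delta = d
            wb[j] = new
        if delta <= tol:
            return 1
    return 0


@njit(cache=True)
def dpr_gibbs_sweep(Rb, bb, wb, assign, sigma2_k, log_pi, kappa, u_cat, z_norm):
    """One collapsed Gibbs sweep over a block for the DP normal-mixture model.

    Model: w_j ~ pi_0 * delta_0 + sum_k pi_k N(0, sigma2_k[k] / kappa),
    i.e. the slab variances are expressed relative to sigma2_eps / n
    (kappa = n / sigma2_eps), with the summary-statistic likelihood
    contribution exp(kappa * s_j * w_j - kappa * w_j^2 / 2) where
    s_j = bb_j - sum_{l != j} Rb_jl w_l.  The relative scaling keeps the
    sampler self-stabilizing when the SNP count approaches the sample
    size: a shrinking residual variance tightens the prior in proportion.

    For each SNP the component assignment is drawn with w_j integrated
    out, then w_j is redrawn from its conjugate normal (or set to 0 for
    the null component).  ``u_cat`` and ``z_norm`` are pre-drawn
    Uniform(0,1) and N(0,1) arrays of length p; ``assign`` is updated in
    place.
    """
    p = wb.shape[0]
    M = sigma2_k.shape[0]  # number of non-null components
    logw = np.empty(M + 1)
    for j in range(p):
        acc = 0.0
        for l in range(p):
            if l != j:
                acc += Rb[j, l] * wb[l]
        s_j = bb[j] - acc
        t_j = kappa * s_j
        # component 0: point mass at zero
        logw[0] = log_pi[0]
        mx = logw[0]
        for k in range(M):
            a_jk = kappa * (1.0 + 1.0 / sigma2_k[k])
            logw[k + 1] = (
                log_pi[k + 1]
                - 0.5 * np.log(1.0 + sigma2_k[k])
                + 0.5 * t_j * t_j / a_jk
            )
            if logw[k + 1] > mx:
                mx = logw[k + 1]
        tot = 0.0
        for k in range(M + 1):
            logw[k] = np.exp(logw[k] - mx)
            tot += logw[k]
        r = u_cat[j] * tot
        cum = 0.0
        pick = M
        for k in range(M + 1):
            cum += logw[k]
            if r <= cum:
                pick = k
                break
        assign[j] = pick
        if pick == 0:
            wb[j] = 0.0
        else:
            a_jk = kappa * (1.0 + 1.0 / sigma2_k[pick - 1])
            wb[j] = t_j / a_jk + z_norm[j] / np.sqrt(a_jk)
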