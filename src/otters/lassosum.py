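"""Summary-statistic LASSO (lassosum-style) with LD shrinkage and
pseudovalidation.

With standardized genotypes and expression, the individual-level LASSO
objective can be rewritten in terms of the marginal effects w_tilde and the
reference LD matrix R_r alone.  Replacing R_r by the shrunken
``R_s = (1 - s) R_r + s I`` gives the convex objective

    f(w) = (1 - s) w' R_r w + s w'w - 2 w_tilde' w + 2 lambda ||w||_1,

minimized by cyclic coordinate descent within LD blocks.  Because R_s has
a unit diagonal for every s, the coordinate update is the exact
soft-threshold step

    w_j <- soft(w_tilde_j - (1 - s) * sum_{k != j} r_jk w_k, lambda).

The (s, lambda) pair is tuned per gene by pseudovalidation: maximize
``pv(w) = w' w_tilde / sqrt(w' R_r w)``, a summary-statistic analogue of
the out-of-sample predictive correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import lassosum_cd_block
from .ldpanel import LDStructure


def _default_lambda_grid() -> list[float]:
    return list(np.logspace(-3, -1, 20))


@dataclass
class LassosumConfig:
    s_grid: list = field(default_factory=lambda: [0.2, 0.5, 0.9, 1.0])
    lambda_grid: list = field(default_factory=_default_lambda_grid)
    max_iter: int = 500
    tol: float = 1e-4  # max absolute coordinate change

    def __post_init__(self) -> None:
        if not self.s_grid or not self.lambda_grid:
            raise ValueError("s_grid and lambda_grid must be non-empty")


def soft_threshold(x: float, lam: float) -> float:
    return np.sign(x) * max(abs(x) - lam, 0.0)


def objective(w: np.ndarray, betas: np.ndarray, R_r: np.ndarray, s: float, lam: float) -> float:
    """The shrunken-LD LASSO objective f(w) (used for monotonicity checks)."""
    return float(
        (1.0 - s) * w @ R_r @ w + s * w @ w - 2.0 * betas @ w + 2.0 * lam * np.abs(w).sum()
    )


def fit_lassosum_single(
    betas: np.ndarray,
    ld: LDStructure,
    s: float,
    lam: float,
    max_iter: int = 500,
    tol: float = 1e-4,
    w0: np.ndarray | None = None,
):
    """Coordinate-descent solution for one (s, lambda) pair.

    Returns ``(w, converged)``.  ``w0`` warm-starts the sweep (used along
    the lambda path).  Each block of ``ld`` is solved independently; with
    ``s = 1`` the problem decouples into elementwise soft-thresholding.
    """
    betas = np.asarray(betas, dtype=float)
    w = np.zeros_like(betas) if w0 is None else np.array(w0, dtype=float)
    if s == 1.0:
        return np.array([soft_threshold(b, lam) for b in betas]), True
    converged = True
    for a, b, Rb in ld.block_matrices():
        wb = np.ascontiguousarray(w[a:b])
        ok = lassosum_cd_block(
            np.ascontiguousarray(Rb), np.ascontiguousarray(betas[a:b]),
            wb, 1.0 - s, lam, max_iter, tol,
        )
        if not ok:
            converged = False
        w[a:b] = wb
    return w, converged


def pseudovalidate(candidates: dict, betas: np.ndarray, ld: LDStructure):
    """Select the (s, lambda) candidate maximizing pv(w) = w'w_tilde / sqrt(w'R_r w).

    All-zero candidates score -inf; ties break toward larger s, then larger
    lambda.  Returns ``((s, lam), w, pv)`` or ``(None, zeros, -inf)`` when
    every candidate is empty.
    """
    betas = np.asarray(betas, dtype=float)
    best_key, best_w, best_pv = None, np.zeros_like(betas), -np.inf
    for (s, lam) in sorted(candidates, key=lambda k: (k[0], k[1])):
        w = candidates[(s, lam)]
        pv = pseudovalidation_score(w, betas, ld)
        if pv >= best_pv and np.isfinite(pv):
            best_key, best_w, best_pv = (s, lam), w, pv
    return best_key, best_w, best_pv


def pseudovalidation_score(w: np.ndarray, betas: np.ndarray, ld: LDStructure) -> float:
    w = np.asarray(w, dtype=float)
    if not np.any(w):
        return -np.inf
    denom = float(w @ ld.R @ w)
    if denom <= 0:
        return -np.inf
    return float(w @ betas) / np.sqrt(denom)


def fit_lassosum(betas: np.ndarray, ld: LDStructure,
                 config: LassosumConfig = None):
    """Full lassosum fit: solve the (s, lambda) grid, pseudovalidate, return weights.

    Returns ``(w, chosen)`` where ``chosen`` is the selected ``(s, lambda)``
    or ``None`` when every candidate was all-zero (empty-gene signal).
    Warm starts run along the lambda path (descending) at fixed s.
    """
    if config is None:
        config = LassosumConfig()
    betas = np.asarray(betas, dtype=float)
    candidates: dict = {}
    for s in config.s_grid:
        w_prev = None
        for lam in sorted(config.lambda_grid, reverse=True):
            w, _ = fit_lassosum_single(
                betas, ld, s, lam, config.max_iter, config.tol, w0=w_prev
            )
            candidates[(s, lam)] = w
            w_prev = w
    chosen, w, _ = pseudovalidate(candidates, betas, ld)
    return w, chosen
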