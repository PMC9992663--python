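"""P+T: LD clumping followed by p-value thresholding.

The simplest summary-statistic weight estimator: clump the cis-window at
r2 > R_T (default 0.99), keep clump-index SNPs with marginal p <= P_T, and
use their marginal standardized effects w_tilde unchanged as weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ldpanel import LDStructure, ld_clump


@dataclass
class PTConfig:
    p_threshold: float = 0.001  # P_T; 0.001 and 0.05 are the standard pair
    r2_threshold: float = 0.99  # R_T

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError(f"p_threshold must be in (0,1], got {self.p_threshold}")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError(f"r2_threshold must be in (0,1], got {self.r2_threshold}")


def fit_pt(betas: np.ndarray, p_values: np.ndarray, ld: LDStructure,
           config: PTConfig = PTConfig()) -> np.ndarray:
    """P+T weights: marginal betas at clump-surviving SNPs with p <= P_T.

    Returns a dense weight vector (zeros elsewhere); all-zero output is a
    valid empty-gene signal.
    """
    betas = np.asarray(betas, dtype=float)
    p_values = np.asarray(p_values, dtype=float)
    w = np.zeros_like(betas)
    if betas.size == 0:
        return w
    kept = ld_clump(p_values, ld.R, config.r2_threshold)
    kept = kept[p_values[kept] <= config.p_threshold]
    w[kept] = betas[kept]
    return w
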