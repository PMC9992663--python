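import numpy as np
import pandas as pd
import pytest

from otters.ldpanel import LDStructure, partition_blocks


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_correlation(m: int, rng, strength: float = 0.5) -> np.ndarray:
    """A random well-conditioned correlation matrix."""
    A = rng.standard_normal((m, m + 5))
    S = A @ A.T / (m + 5) + strength * np.eye(m)
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


@pytest.fixture
def small_ld(rng):
    """A 10-SNP LD structure with its greedy block partition."""
    R = random_correlation(10, rng)
    return LDStructure(R=R, blocks=partition_blocks(R))


def variant_frame(m: int, chrom: str = "1", start: int = 1000, step: int = 100,
                  ref: str = "A", alt: str = "G") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + step * np.arange(m),
            "ref": ref,
            "alt": alt,
        }
    )
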