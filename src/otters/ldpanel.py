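"""Reference genotype panels and linkage-disequilibrium structure.

The LD reference panel supplies everything the summary-statistic weight
estimators need beyond the marginal effects themselves: the m x m SNP
correlation matrix ``R = X'X / n`` of standardized genotypes, a shrunken
version ``R_s = (1 - s) R + s I``, a partition of the cis-window into LD
blocks whose cross-block squared correlation never exceeds a cutoff
(default 0.1), and greedy LD clumping of summary statistics at an r2
threshold (default 0.99).

Genotypes are exchanged as PLINK1 bed/bim/fam triplets (SNP-major 2-bit
encoding); a minimal reader/writer is included here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class GenotypePanel:
    """Sample x SNP allele-count matrix with variant metadata.

    ``dosages`` holds ALT-allele counts in {0,1,2} with NaN for missing
    calls; ``variants`` has columns chrom,pos,ref,alt (ALT is the counted
    allele).
    """

    dosages: np.ndarray  # (n_samples, m_snps) float
    variants: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def m_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, snp_idx) -> "GenotypePanel":
        snp_idx = np.asarray(snp_idx)
        return GenotypePanel(
            dosages=self.dosages[:, snp_idx],
            variants=self.variants.iloc[snp_idx].reset_index(drop=True),
            samples=self.samples,
        )


@dataclass
class LDStructure:
    """Correlation matrix of a cis-window plus its LD-block partition.

    ``R`` is symmetric with unit diagonal; ``blocks`` is an ordered list of
    half-open index ranges partitioning ``range(m)``.  ``shrinkage_s``
    records the convex shrinkage toward the identity already applied.
    """

    R: np.ndarray
    blocks: list[tuple[int, int]] = field(default_factory=list)
    shrinkage_s: float = 0.0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if not self.blocks:
            self.blocks = [(0, self.R.shape[0])]

    @property
    def m(self) -> int:
        return self.R.shape[0]

    def block_matrices(self):
        """Yield (start, stop, R_block) for each block."""
        for a, b in self.blocks:
            yield a, b, self.R[a:b, a:b]


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam IO (SNP-major, PLINK 1.9 layout)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> ALT (A1) allele count; 0b01 is missing
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix) -> GenotypePanel:
    """Read a PLINK1 bed/bim/fam triplet; A1 in the bim is the counted (ALT) allele."""
    prefix = str(prefix)
    bim = pd.read_csv(
        prefix + ".bim",
        sep="\t",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:].reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample-fastest within a byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()  # (n, m)
    variants = pd.DataFrame(
        {
            "chrom": bim["chrom"].astype(str),
            "pos": bim["pos"].astype(int),
            "ref": bim["a2"].astype(str),
            "alt": bim["a1"].astype(str),
        }
    )
    return GenotypePanel(dosages=dosages, variants=variants, samples=list(fam["iid"]))


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write a PLINK1 bed/bim/fam triplet (ALT stored as A1)."""
    prefix = str(prefix)
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    v = panel.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"].astype(str),
            "snp_id": [
                f"{c}:{p}:{r}:{a}"
                for c, p, r, a in zip(v["chrom"], v["pos"], v["ref"], v["alt"])
            ],
            "cm": 0,
            "pos": v["pos"].astype(int),
            "a1": v["alt"],
            "a2": v["ref"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    samples = panel.samples or [f"S{i+1}" for i in range(panel.n_samples)]
    fam = pd.DataFrame(
        {"fid": samples, "iid": samples, "father": "0", "mother": "0", "sex": "0", "pheno": "-9"}
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)

    n, m = panel.n_samples, panel.m_snps
    dos = panel.dosages
    codes = np.full((m, n), 1, dtype=np.uint8)  # 0b01 = missing
    codes[:, :] = np.where(np.isnan(dos.T), 1, np.select(
        [dos.T == 2, dos.T == 1, dos.T == 0], [0, 2, 3], default=1
    )).astype(np.uint8)
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    packed = (
        codes[:, 0::4] | (codes[:, 1::4] << 2) | (codes[:, 2::4] << 4) | (codes[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def query_region(panel: GenotypePanel, chrom, start: int, end: int) -> GenotypePanel:
    """Subset a panel to variants in a 1-based inclusive interval."""
    v = panel.variants
    mask = (v["chrom"].astype(str) == str(chrom)) & (v["pos"] >= start) & (v["pos"] <= end)
    return panel.subset(np.flatnonzero(mask.to_numpy()))


# ---------------------------------------------------------------------------
# standardization and LD
# ---------------------------------------------------------------------------

def standardize(panel: GenotypePanel):
    """Mean-impute missing dosages, then scale each SNP to mean 0, variance 1.

    Variance uses denominator ``n`` so that ``X'X / n`` has an exactly unit
    diagonal.  Monomorphic SNPs (zero variance after imputation) are
    dropped with a warning.

    Returns
    -------
    (X, kept_idx, sd) : standardized matrix, indices of retained SNPs in
    the input panel, and the per-SNP dosage standard deviations sigma_j.
    """
    dos = np.array(panel.dosages, dtype=float)
    col_mean = np.nanmean(dos, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(dos))
    dos[nan_r, nan_c] = col_mean[nan_c]
    mean = dos.mean(axis=0)
    sd = dos.std(axis=0)  # ddof=0
    kept = np.flatnonzero(sd > 0)
    if len(kept) < dos.shape[1]:
        warnings.warn(
            f"dropped {dos.shape[1] - len(kept)} monomorphic SNP(s)", stacklevel=2
        )
    X = (dos[:, kept] - mean[kept]) / sd[kept]
    return X, kept, sd[kept]


def compute_ld(X_std: np.ndarray) -> LDStructure:
    """LD correlation matrix ``R = X'X / n`` of a standardized panel."""
    n = X_std.shape[0]
    R = (X_std.T @ X_std) / n
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return LDStructure(R=R)


def shrink_ld(R_r: np.ndarray, s: float) -> np.ndarray:
    """Convex shrinkage toward the identity: ``R_s = (1 - s) R_r + s I``."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"shrinkage s must lie in [0, 1], got {s}")
    R_r = np.asarray(R_r, dtype=float)
    return (1.0 - s) * R_r + s * np.eye(R_r.shape[0])


def partition_blocks(R: np.ndarray, r2_cross: float = 0.1) -> list[tuple[int, int]]:
    """Greedy left-to-right partition into LD blocks.

    A cut is placed at the earliest position such that no SNP left of the
    cut has squared correlation above ``r2_cross`` with any SNP at or right
    of it, which guarantees every cross-block pair satisfies
    ``r2 <= r2_cross``.
    """
    R = np.asarray(R)
    m = R.shape[0]
    r2 = R * R
    # reach[i] = last index k with r2(i,k) > cutoff (at least i itself)
    reach = np.empty(m, dtype=np.int64)
    for i in range(m):
        above = np.flatnonzero(r2[i] > r2_cross)
        reach[i] = above[-1] if len(above) else i
    blocks = []
    start = 0
    running = -1
    for j in range(m):
        running = max(running, reach[j])
        if running <= j:  # no SNP <= j correlates past j: cut after j
            blocks.append((start, j + 1))
            start = j + 1
    if start < m:  # pragma: no cover - loop above always closes the last block
        blocks.append((start, m))
    return blocks


def load_blocks_bed(path, variants: pd.DataFrame) -> list[tuple[int, int]]:
    """Convert 3-column BED block boundaries (0-based half-open) to index ranges."""
    bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"],
                      dtype={"chrom": str})
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].astype(str).to_numpy()
    assigned = np.full(len(variants), -1, dtype=int)
    for bi, row in enumerate(bed.itertuples(index=False)):
        inside = (chrom == str(row.chrom)) & (pos > row.start) & (pos <= row.end)
        assigned[inside & (assigned < 0)] = bi
    blocks: list[tuple[int, int]] = []
    start = 0
    for j in range(1, len(assigned)):
        if assigned[j] != assigned[j - 1]:
            blocks.append((start, j))
            start = j
    if len(assigned):
        blocks.append((start, len(assigned)))
    return blocks


def ld_clump(p_values: np.ndarray, R: np.ndarray, r2_threshold: float = 0.99) -> np.ndarray:
    """Greedy LD clumping: indices of retained SNPs.

    SNPs are visited by ascending p-value (ties broken by position order,
    i.e. input index); each retained SNP removes all not-yet-retained SNPs
    with ``r2 > r2_threshold`` to it.  The result is sorted by index and is
    independent of the input row order by construction.
    """
    p = np.asarray(p_values, dtype=float)
    r2 = np.asarray(R) ** 2
    order = np.lexsort((np.arange(len(p)), p))
    alive = np.ones(len(p), dtype=bool)
    kept = []
    for j in order:
        if not alive[j]:
            continue
        kept.append(j)
        alive &= ~(r2[j] > r2_threshold)
        alive[j] = False
    return np.array(sorted(kept), dtype=int)
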