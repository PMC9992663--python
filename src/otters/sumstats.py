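"""Reading, validation and harmonization of summary-level eQTL/GWAS statistics.

Summary eQTL data report, per SNP ``j``, the marginal association with a
gene's expression from the single-variant model ``e_g = x_j w_j + eps_j``:
a Z-score ``Z_j`` (or beta/SE pair), a p-value, and a per-SNP sample size
``n_{g,j}``.  On the standardized-genotype, standardized-expression scale
the marginal effect is approximated by ``w_tilde_j = Z_j / sqrt(median_n)``
where ``median_n`` is the median cis-SNP sample size of the gene — a single
robust sample-size value reused by every downstream weight estimator.

Files are plain tab-delimited with a header (gzip transparently supported
through pandas).  Required columns:

* eQTL:  CHROM POS REF ALT GENE  and  Z  (or BETA+SE), P, N
* GWAS:  CHROM POS REF ALT Z N
* weights: CHROM POS REF ALT GENE METHOD WEIGHT
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: strand-ambiguous (palindromic) allele pairs
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]


class SumStatsFormatError(ValueError):
    """Malformed summary-statistic or weight file."""


@dataclass
class EQTLSumStats:
    """Per-gene single-SNP eQTL association results within the cis-window."""

    gene_id: str
    table: pd.DataFrame  # chrom,pos,ref,alt,z,beta_marginal,p,n
    n_median: int = 0

    def __post_init__(self) -> None:
        if len(self.table) and self.n_median == 0:
            self.n_median = int(np.median(self.table["n"]))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def empty(self) -> bool:
        return len(self.table) == 0


@dataclass
class GWASSumStats:
    """Genome- or region-wide single-SNP GWAS Z-scores."""

    table: pd.DataFrame  # chrom,pos,ref,alt,z,n

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class EQTLWeights:
    """Per-gene eQTL weight vector from one training method.

    Weights live on the standardized-genotype, standardized-expression
    scale.  Zero-weight SNPs may simply be absent.
    """

    gene_id: str
    method: str
    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=VARIANT_KEY + ["weight"])
    )

    def __len__(self) -> int:
        return len(self.table)


def marginal_std_beta(z, n_median: int):
    """Marginal standardized effect ``w_tilde = z / sqrt(n_median)``.

    Linear in ``z``; ``n_median`` must be at least 2.
    """
    if n_median < 2:
        raise ValueError(f"n_median must be >= 2, got {n_median}")
    return np.asarray(z, dtype=float) / math.sqrt(n_median) if np.ndim(z) else z / math.sqrt(n_median)


def _check_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise SumStatsFormatError(f"{path}: missing required column(s) {sorted(missing)}")


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.rename(columns={c: c.lower() for c in df.columns})
    df = df.rename(columns={"chrom": "chrom", "#chrom": "chrom"})
    df["chrom"] = df["chrom"].astype(str)
    for col in ("ref", "alt"):
        df[col] = df[col].astype(str).str.upper()
    return df


def read_eqtl_sumstats(path, gene_id: str, cis_window) -> EQTLSumStats:
    """Read one gene's cis-eQTL summary statistics.

    Parameters
    ----------
    path : str
        Tab-delimited file with header; may contain several genes.
    gene_id : str
        Gene to extract.
    cis_window : (chrom, start, end)
        1-based inclusive interval; rows outside it are discarded.

    Either a ``Z`` column or a ``BETA``/``SE`` pair must be present; in the
    latter case ``z = beta / se``.  Rows with neither are dropped (counted
    in the log).  An empty result is a valid empty-gene signal, not an error.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    raw.columns = [c.upper().lstrip("#") for c in raw.columns]
    _check_columns(raw, {"CHROM", "POS", "REF", "ALT", "GENE", "P", "N"}, path)
    has_z = "Z" in raw.columns
    has_bse = {"BETA", "SE"}.issubset(raw.columns)
    if not has_z and not has_bse:
        raise SumStatsFormatError(f"{path}: need a Z column or BETA+SE columns")

    df = raw[raw["GENE"] == gene_id].copy()
    chrom, start, end = cis_window
    df = df[(df["CHROM"].astype(str) == str(chrom)) & (df["POS"] >= start) & (df["POS"] <= end)]

    if has_z:
        z = pd.to_numeric(df["Z"], errors="coerce")
    else:
        z = pd.Series(np.nan, index=df.index)
    if has_bse:
        bz = pd.to_numeric(df["BETA"], errors="coerce") / pd.to_numeric(df["SE"], errors="coerce")
        z = z.fillna(bz)
    n_dropped = int(z.isna().sum())
    if n_dropped:
        log.info("%s: dropped %d rows with no usable Z or BETA/SE", gene_id, n_dropped)
    df = df[z.notna()]
    z = z[z.notna()]

    out = pd.DataFrame(
        {
            "chrom": df["CHROM"].astype(str).values,
            "pos": df["POS"].astype(int).values,
            "ref": df["REF"].astype(str).str.upper().values,
            "alt": df["ALT"].astype(str).str.upper().values,
            "z": z.astype(float).values,
            "p": pd.to_numeric(df["P"]).astype(float).values,
            "n": df["N"].astype(int).values,
        }
    )
    if out.duplicated(subset=VARIANT_KEY).any():
        raise SumStatsFormatError(f"{path}: duplicate variant keys for gene {gene_id}")
    ss = EQTLSumStats(gene_id=gene_id, table=out)
    if len(out):
        ss.table["beta_marginal"] = marginal_std_beta(out["z"].values, ss.n_median)
    else:
        ss.table["beta_marginal"] = np.array([], dtype=float)
    return ss


def read_gwas_sumstats(path) -> GWASSumStats:
    """Read GWAS summary statistics (CHROM POS REF ALT Z N)."""
    raw = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    raw.columns = [c.upper().lstrip("#") for c in raw.columns]
    _check_columns(raw, {"CHROM", "POS", "REF", "ALT", "Z", "N"}, path)
    out = pd.DataFrame(
        {
            "chrom": raw["CHROM"].astype(str).values,
            "pos": raw["POS"].astype(int).values,
            "ref": raw["REF"].astype(str).str.upper().values,
            "alt": raw["ALT"].astype(str).str.upper().values,
            "z": pd.to_numeric(raw["Z"]).astype(float).values,
            "n": raw["N"].astype(int).values,
        }
    )
    if out.duplicated(subset=VARIANT_KEY).any():
        raise SumStatsFormatError(f"{path}: duplicate variant keys")
    if not np.isfinite(out["z"]).all():
        raise SumStatsFormatError(f"{path}: non-finite Z values")
    return GWASSumStats(table=out)


def harmonize(table: pd.DataFrame, panel_variants: pd.DataFrame):
    """Align a summary-statistic table to a reference panel's variants.

    Matching is by (chrom, pos).  Exact ref/alt matches are kept; swapped
    alleles are kept with ``z`` (and ``beta_marginal`` if present) sign
    flipped; strand-ambiguous (A/T, C/G) and otherwise mismatched or
    unmatched variants are dropped.  The returned table is ordered by the
    panel's variant order and carries a ``panel_idx`` column.

    Returns
    -------
    (harmonized, report) : (pd.DataFrame, dict)
        ``report`` counts ``matched``, ``flipped``, ``ambiguous``,
        ``mismatched`` and ``unmatched`` variants.
    """
    panel = panel_variants.reset_index(drop=True)
    panel_map = {
        (str(c), int(p)): (i, r, a)
        for i, (c, p, r, a) in enumerate(
            zip(panel["chrom"].astype(str), panel["pos"], panel["ref"], panel["alt"])
        )
    }
    report = {"matched": 0, "flipped": 0, "ambiguous": 0, "mismatched": 0, "unmatched": 0}
    rows, order = [], []
    flip_cols = [c for c in ("z", "beta_marginal", "weight") if c in table.columns]
    for row in table.itertuples(index=False):
        key = (str(row.chrom), int(row.pos))
        hit = panel_map.get(key)
        if hit is None:
            report["unmatched"] += 1
            continue
        idx, pref, palt = hit
        ref, alt = str(row.ref), str(row.alt)
        if (ref, alt) in _AMBIGUOUS:
            report["ambiguous"] += 1
            continue
        if (ref, alt) == (pref, palt):
            report["matched"] += 1
            d = row._asdict()
        elif (alt, ref) == (pref, palt):
            report["flipped"] += 1
            d = row._asdict()
            d["ref"], d["alt"] = pref, palt
            for c in flip_cols:
                d[c] = -d[c]
        else:
            report["mismatched"] += 1
            continue
        d["panel_idx"] = idx
        rows.append(d)
        order.append(idx)
    if rows:
        out = pd.DataFrame(rows).iloc[np.argsort(order, kind="stable")].reset_index(drop=True)
    else:
        out = pd.DataFrame(columns=list(table.columns) + ["panel_idx"])
    return out, report


def write_weights(weights: EQTLWeights, path) -> None:
    """Write a weight file (refuses non-finite weights)."""
    tab = weights.table
    if len(tab) and not np.isfinite(tab["weight"].to_numpy(dtype=float)).all():
        raise ValueError(f"{weights.gene_id}/{weights.method}: non-finite weight")
    if len(tab) and tab.duplicated(subset=VARIANT_KEY).any():
        raise ValueError(f"{weights.gene_id}/{weights.method}: duplicate variant keys")
    out = pd.DataFrame(
        {
            "CHROM": tab["chrom"].astype(str) if len(tab) else [],
            "POS": tab["pos"].astype(int) if len(tab) else [],
            "REF": tab["ref"] if len(tab) else [],
            "ALT": tab["alt"] if len(tab) else [],
            "GENE": weights.gene_id,
            "METHOD": weights.method,
            "WEIGHT": tab["weight"].astype(float) if len(tab) else [],
        }
    )
    if not len(tab):  # header-only file for an empty weight set
        out = pd.DataFrame(columns=["CHROM", "POS", "REF", "ALT", "GENE", "METHOD", "WEIGHT"])
    out.to_csv(path, sep="\t", index=False)


def read_weights(path) -> EQTLWeights:
    """Read a weight file written by :func:`write_weights` (single gene+method)."""
    try:
        raw = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SumStatsFormatError(f"{path}: unreadable weight file ({exc})") from exc
    raw.columns = [c.upper() for c in raw.columns]
    _check_columns(raw, {"CHROM", "POS", "REF", "ALT", "GENE", "METHOD", "WEIGHT"}, path)
    if raw.empty:
        return EQTLWeights(gene_id="", method="")
    genes = raw["GENE"].unique()
    methods = raw["METHOD"].unique()
    if len(genes) != 1 or len(methods) != 1:
        raise SumStatsFormatError(f"{path}: expected a single gene/method per file")
    tab = pd.DataFrame(
        {
            "chrom": raw["CHROM"].astype(str).values,
            "pos": raw["POS"].astype(int).values,
            "ref": raw["REF"].astype(str).values,
            "alt": raw["ALT"].astype(str).values,
            "weight": pd.to_numeric(raw["WEIGHT"]).astype(float).values,
        }
    )
    return EQTLWeights(gene_id=str(genes[0]), method=str(methods[0]), table=tab)
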