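"""Reading and harmonizing GWAS summary statistics.

Two GWAS are joined on shared SNP identifiers, filtered by an allele-match
policy, and their p-values are converted into signed score vectors

    w_i = sign(beta_i) * sqrt( inv-chi2_1(1 - p_i) ),

optionally after a rank-based (qq) normalization that re-assigns the p-values
of each trait over the shared SNP set to the uniform grid (r+1)/(N+1).  The
qq transform equalizes the signal strength of the two studies, which is what
makes the multiplicative combination of a very well-powered GWAS with a small
one behave sensibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "harmonize_pair",
    "transform_scores",
    "qq_normalize",
    "HarmonizedPair",
    "DEFAULT_COLUMNS",
    "GwasIOError",
    "EmptyOverlapError",
]

logger = logging.getLogger(__name__)

#: default header names for summary-statistics TSV files
DEFAULT_COLUMNS: Mapping[str, str] = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "a1": "a1",
    "a2": "a2",
    "pval": "pval",
    "beta": "beta",
}


class GwasIOError(ValueError):
    """Malformed input or configuration."""


class EmptyOverlapError(GwasIOError):
    """No SNPs survived intersection/harmonization."""


@dataclass
class HarmonizedPair:
    """Allele-matched SNPs shared by two GWAS, with per-trait p and sign.

    ``w`` and ``z`` are filled by :func:`transform_scores`.
    """

    table: pd.DataFrame  # snp_id chrom pos p_a sign_a p_b sign_b
    n_input_a: int
    n_input_b: int
    n_allele_mismatch: int
    w: np.ndarray | None = None
    z: np.ndarray | None = None
    normalization: str | None = None
    dropped_signless: int = 0

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    @property
    def n_shared(self) -> int:
        return len(self.table)


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = "\t",
) -> pd.DataFrame:
    """Read a headered (tab-separated by default) summary-statistics table.

    Returns a DataFrame with canonical columns
    ``snp_id chrom pos a1 a2 pval beta_sign`` in file order.  Rows with a
    missing or unparseable p-value or effect size are dropped and counted in
    the log.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    try:
        raw = pd.read_csv(path, sep=sep if sep is not None else r"\s+",
                          dtype=str, engine="python" if sep is None else "c")
    except pd.errors.EmptyDataError as exc:
        raise GwasIOError(f"empty summary-statistics file: {path}") from exc
    if raw.empty:
        raise GwasIOError(f"no data rows in summary-statistics file: {path}")
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise GwasIOError(
            f"{path}: mapped columns {missing} not found in header {list(raw.columns)}"
        )
    df = pd.DataFrame(
        {
            "snp_id": raw[cmap["snp_id"]].astype(str),
            "chrom": raw[cmap["chrom"]].astype(str),
            "pos": pd.to_numeric(raw[cmap["pos"]], errors="coerce"),
            "a1": raw[cmap["a1"]].astype(str).str.upper(),
            "a2": raw[cmap["a2"]].astype(str).str.upper(),
            "pval": pd.to_numeric(raw[cmap["pval"]], errors="coerce"),
            "beta": pd.to_numeric(raw[cmap["beta"]], errors="coerce"),
        }
    )
    ok = (
        df["pval"].notna()
        & df["beta"].notna()
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & df["pos"].notna()
    )
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("%s: dropped %d rows with missing/invalid p or beta", path, n_drop)
    df = df[ok].reset_index(drop=True)
    if df.empty:
        raise GwasIOError(f"all rows of {path} were invalid")
    df["pos"] = df["pos"].astype(np.int64)
    df["beta_sign"] = np.sign(df["beta"]).astype(np.int8)
    return df.drop(columns="beta")


def write_summary_stats(df: pd.DataFrame, path) -> None:
    """Write a canonical summary-statistics table (TSV, 1-based positions)."""
    df.to_csv(path, sep="\t", index=False)


def harmonize_pair(
    a: pd.DataFrame,
    b: pd.DataFrame,
    policy: Literal["strict", "swap_flip"] = "strict",
) -> HarmonizedPair:
    """Intersect two GWAS on SNP id and apply the allele-match policy.

    ``strict`` keeps SNPs whose (a1, a2) pairs are identical in both GWAS;
    ``swap_flip`` additionally keeps (a1, a2) vs (a2, a1) pairs, negating the
    second GWAS's sign.  Mismatches are counted in ``n_allele_mismatch``.
    """
    if policy not in ("strict", "swap_flip"):
        raise GwasIOError(f"unknown allele policy {policy!r}")
    if a.empty or b.empty:
        raise GwasIOError("both summary-statistics tables must be non-empty")
    merged = a.merge(b, on="snp_id", suffixes=("_a", "_b"), how="inner")
    if merged.empty:
        raise EmptyOverlapError(
            f"no shared SNP ids between the two GWAS ({len(a)} vs {len(b)} input SNPs)"
        )
    same = (merged["a1_a"] == merged["a1_b"]) & (merged["a2_a"] == merged["a2_b"])
    if policy == "strict":
        keep = merged[same].copy()
        keep["sign_b_adj"] = keep["beta_sign_b"]
    else:
        swapped = (merged["a1_a"] == merged["a2_b"]) & (merged["a2_a"] == merged["a1_b"])
        swapped &= ~same  # A/A degenerate alleles cannot be both
        keep = merged[same | swapped].copy()
        keep["sign_b_adj"] = np.where(
            swapped[same | swapped], -keep["beta_sign_b"], keep["beta_sign_b"]
        )
    n_mismatch = len(merged) - len(keep)
    if n_mismatch:
        logger.info("harmonize_pair: %d shared SNPs dropped for allele mismatch",
                    n_mismatch)
    if keep.empty:
        raise EmptyOverlapError("no shared SNPs passed the allele-match policy")
    table = pd.DataFrame(
        {
            "snp_id": keep["snp_id"],
            "chrom": keep["chrom_a"],
            "pos": keep["pos_a"],
            "p_a": keep["pval_a"],
            "sign_a": keep["beta_sign_a"].astype(np.int8),
            "p_b": keep["pval_b"],
            "sign_b": keep["sign_b_adj"].astype(np.int8),
        }
    ).reset_index(drop=True)
    return HarmonizedPair(
        table=table,
        n_input_a=len(a),
        n_input_b=len(b),
        n_allele_mismatch=n_mismatch,
    )


def qq_normalize(
    pvals: np.ndarray,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
) -> np.ndarray:
    """Rank-based re-assignment of p-values to the uniform grid (r+1)/(N+1).

    Ranks are ordinal (stable); ties are broken by genomic coordinate when
    given, so the output is deterministic.  The output is a permutation of
    {(k+1)/(N+1) : k = 0..N-1} and preserves the input ordering of evidence.
    """
    pvals = np.asarray(pvals, dtype=float)
    n = pvals.size
    if chrom is not None and pos is not None:
        order = np.lexsort((np.asarray(pos), np.asarray(chrom, dtype="U"), pvals))
    else:
        order = np.argsort(pvals, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks + 1.0) / (n + 1.0)


def transform_scores(
    pair: HarmonizedPair,
    strategy: Literal["qq", "cutoff", "raw"] = "qq",
    cutoff: float = 1e-16,
) -> HarmonizedPair:
    """Fill the signed score vectors (w, z) of a harmonized pair.

    Per trait, p-values over the shared SNP set are first moderated by the
    chosen strategy (``qq`` rank transform, hard ``cutoff``, or ``raw``), then
    converted to magnitudes via the inverse chi2_1 cdf and signed by the
    effect direction.  SNPs with a zero effect sign in either trait carry no
    direction information and are dropped (counted in ``dropped_signless``).
    """
    if strategy not in ("qq", "cutoff", "raw"):
        raise GwasIOError(f"unknown normalization strategy {strategy!r}")
    if strategy == "cutoff" and not 0.0 < cutoff < 1.0:
        raise GwasIOError("cutoff must lie in (0, 1)")
    table = pair.table
    signed = (table["sign_a"] != 0) & (table["sign_b"] != 0)
    n_signless = int((~signed).sum())
    if n_signless:
        logger.info("transform_scores: dropped %d SNPs with zero effect sign",
                    n_signless)
    table = table[signed].reset_index(drop=True)
    if table.empty:
        raise EmptyOverlapError("all shared SNPs lack an effect direction")
    out = {}
    for trait, pcol, scol in (("w", "p_a", "sign_a"), ("z", "p_b", "sign_b")):
        p = table[pcol].to_numpy(dtype=float)
        if strategy == "qq":
            p = qq_normalize(p, table["chrom"].to_numpy(), table["pos"].to_numpy())
        elif strategy == "cutoff":
            p = np.maximum(p, cutoff)
        out[trait] = table[scol].to_numpy(dtype=float) * np.sqrt(
            stats.chi2.isf(p, df=1)
        )
    new_table = table.copy()
    return replace(
        pair,
        table=new_table,
        w=out["w"],
        z=out["z"],
        normalization=strategy,
        dropped_signless=n_signless,
    )
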