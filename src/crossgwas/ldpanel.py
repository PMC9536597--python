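"""Reference-panel LD: per-gene SNP-SNP correlation matrices and their spectra.

The null distribution of every gene-level statistic in this package is fully
determined by the eigenvalues of the SNP-SNP correlation matrix Sigma of the
gene window, estimated from an external genotype reference panel as
Sigma = x'x / n on mean-imputed, standardized dosage columns.  Eigenvalues
below a small threshold (default 1e-8, after clipping negative round-off to
zero) span directions that carry no signal and are excluded from all tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneWindow",
    "CorrelationStructure",
    "ReferencePanel",
    "load_panel",
    "correlation_matrix",
    "build_null_covariance",
    "read_gene_annotation",
    "PanelError",
    "EIGENVALUE_TOL",
    "DEFAULT_WINDOW_BP",
]

logger = logging.getLogger(__name__)

EIGENVALUE_TOL = 1e-8
DEFAULT_WINDOW_BP = 50_000


class PanelError(ValueError):
    """Malformed panel, annotation, or degenerate correlation request."""


@dataclass(frozen=True)
class GeneWindow:
    """A gene's transcript span extended by ``window_bp`` on both sides."""

    gene_id: str
    chrom: str
    start: int  # 1-based, transcript start - window, clipped at 1
    end: int
    window_bp: int = DEFAULT_WINDOW_BP

    @classmethod
    def from_transcript(cls, gene_id, chrom, tx_start, tx_end,
                        window_bp: int = DEFAULT_WINDOW_BP) -> "GeneWindow":
        if tx_end < tx_start:
            tx_start, tx_end = tx_end, tx_start
        return cls(str(gene_id), str(chrom), max(1, int(tx_start) - window_bp),
                   int(tx_end) + window_bp, window_bp)

    def overlaps(self, other: "GeneWindow") -> bool:
        return self.chrom == other.chrom and not (
            self.end < other.start or other.end < self.start
        )


@dataclass
class CorrelationStructure:
    """A symmetric SNP-SNP matrix with its eigensystem and Cholesky factor.

    ``eigvals``/``eigvecs`` hold only the retained eigenpairs (those at least
    ``EIGENVALUE_TOL`` after clipping negatives to zero); ``dropped_dims``
    counts the excluded near-null directions.  ``chol`` factors the
    regularized matrix (a ridge of 1e-8 is added when the matrix is singular).
    """

    snp_ids: list[str]
    sigma: np.ndarray
    eigvals: np.ndarray = field(init=False)
    eigvecs: np.ndarray = field(init=False)
    chol: np.ndarray = field(init=False)
    dropped_dims: int = field(init=False)

    def __post_init__(self):
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
            raise PanelError("sigma must be a square matrix")
        if len(self.snp_ids) != sigma.shape[0]:
            raise PanelError("snp_ids and sigma dimensions disagree")
        self.sigma = (sigma + sigma.T) / 2.0
        vals, vecs = np.linalg.eigh(self.sigma)
        vals = np.clip(vals, 0.0, None)
        keep = vals >= EIGENVALUE_TOL
        self.dropped_dims = int((~keep).sum())
        order = np.argsort(vals[keep])[::-1]
        self.eigvals = vals[keep][order]
        self.eigvecs = vecs[:, keep][:, order]
        if self.eigvals.size == 0:
            raise PanelError("correlation matrix has no retained eigenvalues")
        try:
            self.chol = np.linalg.cholesky(self.sigma)
        except np.linalg.LinAlgError:
            self.chol = np.linalg.cholesky(
                self.sigma + EIGENVALUE_TOL * np.eye(self.sigma.shape[0])
            )

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def decorrelate(self, v: np.ndarray) -> np.ndarray:
        """Rotate a score vector into the retained eigenbasis (v-bar = U'v)."""
        return self.eigvecs.T @ np.asarray(v, dtype=float)


class ReferencePanel:
    """In-memory dosage matrix (samples x SNPs) with positional indexing."""

    def __init__(self, dosages: np.ndarray, snp_ids, chrom=None, pos=None):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise PanelError("dosage matrix must be 2-dimensional")
        if dosages.shape[0] == 0:
            raise PanelError("reference panel has no samples")
        if dosages.shape[1] != len(snp_ids):
            raise PanelError("dosage columns and snp ids disagree")
        self.dosages = dosages
        self.snp_ids = [str(s) for s in snp_ids]
        self.chrom = np.asarray([str(c) for c in chrom]) if chrom is not None else None
        self.pos = np.asarray(pos, dtype=np.int64) if pos is not None else None
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def columns(self, snp_ids) -> tuple[list[str], np.ndarray]:
        """Dosage columns for the panel-present subset of ``snp_ids``."""
        present = [s for s in snp_ids if s in self._index]
        idx = [self._index[s] for s in present]
        return present, self.dosages[:, idx]

    def snps_in_interval(self, chrom: str, start: int, end: int) -> list[str]:
        """SNP ids with start <= pos <= end on ``chrom`` (empty if none)."""
        if self.chrom is None or self.pos is None:
            raise PanelError("panel has no positional information")
        mask = (self.chrom == str(chrom)) & (self.pos >= start) & (self.pos <= end)
        return [self.snp_ids[i] for i in np.flatnonzero(mask)]


def _load_matrix_panel(path) -> ReferencePanel:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise PanelError(f"empty panel file: {path}") from exc
    if df.empty:
        raise PanelError(f"no samples in panel file: {path}")
    return ReferencePanel(df.to_numpy(dtype=float), list(df.columns))


def _load_vcf_panel(path) -> ReferencePanel:
    from cyvcf2 import VCF

    ids, chroms, poss, cols = [], [], [], []
    vcf = VCF(str(path), gts012=True)
    if len(vcf.samples) == 0:
        raise PanelError(f"no samples in VCF: {path}")
    for var in vcf:
        if len(var.ALT) != 1:
            logger.info("skipping multiallelic site %s:%d", var.CHROM, var.POS)
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = unknown
        gt[gt == 3] = np.nan
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        cols.append(gt)
    if not cols:
        raise PanelError(f"no usable biallelic sites in VCF: {path}")
    return ReferencePanel(np.column_stack(cols), ids, chroms, poss)


def load_panel(path, format: str = "matrix") -> ReferencePanel:
    """Load a genotype reference panel.

    ``matrix``: TSV whose header row holds SNP ids and each following row one
    sample's 0/1/2 dosages (no positional index).  ``vcf``: standard VCF with
    GT fields; phased genotypes are collapsed to dosages and multiallelic
    sites are skipped.
    """
    if format == "matrix":
        return _load_matrix_panel(path)
    if format == "vcf":
        return _load_vcf_panel(path)
    raise PanelError(f"unknown panel format {format!r}")


def _standardize(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing calls, center, and scale columns to unit variance.

    Returns the standardized matrix and a boolean mask of non-monomorphic
    columns (monomorphic SNPs cannot be standardized and are dropped).
    """
    geno = np.array(geno, dtype=float)
    col_mean = np.nanmean(geno, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(geno))
    geno[nan_r, nan_c] = col_mean[nan_c]
    centered = geno - geno.mean(axis=0)
    sd = centered.std(axis=0, ddof=0)
    keep = sd > 0
    out = np.zeros_like(centered)
    out[:, keep] = centered[:, keep] / sd[keep]
    return out[:, keep], keep


def correlation_matrix(panel: ReferencePanel, snp_ids) -> CorrelationStructure:
    """Sigma = x'x / n over the panel-present, non-monomorphic subset."""
    present, geno = panel.columns(snp_ids)
    if not present:
        raise PanelError("none of the requested SNPs are present in the panel")
    std, keep = _standardize(geno)
    n_mono = int((~keep).sum())
    if n_mono:
        logger.info("correlation_matrix: dropped %d monomorphic SNPs", n_mono)
    kept_ids = [s for s, k in zip(present, keep) if k]
    if not kept_ids:
        raise PanelError("all requested SNPs are monomorphic in the panel")
    sigma = std.T @ std / panel.n_samples
    return CorrelationStructure(kept_ids, sigma)


def build_null_covariance(
    sigma_struct: CorrelationStructure,
    panel: ReferencePanel,
    h2: float,
    window_bp: int = DEFAULT_WINDOW_BP,
    chrom: str | None = None,
    interval: tuple[int, int] | None = None,
) -> CorrelationStructure:
    """Spectral structure of the random-effect null h2 * L + Sigma.

    L = x' X X' x / (n p) couples the gene's SNPs (columns x) to the flanking
    SNPs X within ``window_bp`` of the gene window; with polygenic effects of
    total heritability h2 the null covariance of the score vector becomes
    h2 * L + Sigma.  ``h2 = 0`` returns the input structure unchanged.
    """
    if not 0.0 <= h2 < 1.0:
        raise PanelError("h2 must lie in [0, 1)")
    if h2 == 0.0:
        return sigma_struct
    if chrom is not None and interval is not None and panel.pos is not None:
        lo, hi = interval
        flank_ids = panel.snps_in_interval(chrom, lo - window_bp, hi + window_bp)
    else:
        flank_ids = panel.snp_ids  # no positional info: use the whole panel
    _, flank = panel.columns(flank_ids)
    flank_std, _ = _standardize(flank)
    _, gene = panel.columns(sigma_struct.snp_ids)
    gene_std, _ = _standardize(gene)
    n = panel.n_samples
    p = flank_std.shape[1]
    if p == 0:
        raise PanelError("no flanking SNPs available for the L matrix")
    cross = gene_std.T @ flank_std / n  # x'X / n
    L = cross @ cross.T * n / p
    return CorrelationStructure(list(sigma_struct.snp_ids),
                                h2 * L + sigma_struct.sigma)


def read_gene_annotation(path, window_bp: int = DEFAULT_WINDOW_BP) -> list[GeneWindow]:
    """Read a gene annotation TSV (gene_id, chrom, tx_start, tx_end; 1-based)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tx_start", "tx_end"}
    if not required.issubset(df.columns):
        raise PanelError(
            f"gene annotation {path} must have columns {sorted(required)}"
        )
    return [
        GeneWindow.from_transcript(r.gene_id, r.chrom, r.tx_start, r.tx_end, window_bp)
        for r in df.itertuples()
    ]
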