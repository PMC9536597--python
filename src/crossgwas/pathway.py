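"""Pathway (gene-set) enrichment of gene-level coherence or ratio scores.

Gene scores within a pathway are not independent when member genes share SNPs
through overlapping (extended) windows.  Members whose +/-window regions
overlap on the same chromosome are therefore fused into *meta-genes*
(single-linkage) and re-scored jointly on the union of their SNPs.  The
pathway statistic is then the classic rank-normalized chi-square sum: all
genome-wide gene p-values are qq-normalized, each pathway (meta-)gene's
normalized p is mapped to a chi2_1 quantile, and the sum of the n quantiles
is tested against chi2_n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .gwas_io import qq_normalize
from .ldpanel import GeneWindow

__all__ = [
    "GeneSet",
    "MetaGene",
    "read_gmt",
    "fuse_meta_genes",
    "pathway_enrichment",
    "PathwayError",
]

logger = logging.getLogger(__name__)


class PathwayError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    gene_ids: frozenset[str]
    description: str = ""

    def __post_init__(self):
        if not self.gene_ids:
            raise PathwayError(f"gene set {self.name!r} is empty")


@dataclass
class MetaGene:
    """A fusion of pathway member genes with transitively overlapping windows."""

    member_gene_ids: list[str]
    fused_window: GeneWindow

    @property
    def meta_id(self) -> str:
        return "+".join(self.member_gene_ids)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, tab-separated ids)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise PathwayError(f"{path}:{lineno}: GMT line has fewer than 2 fields")
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                logger.info("%s:%d: gene set %s has no genes, skipped",
                            path, lineno, parts[0])
                continue
            sets.append(GeneSet(parts[0], genes, parts[1]))
    return sets


def fuse_meta_genes(genes: list[GeneWindow], gene_set: GeneSet) -> list[MetaGene]:
    """Single-linkage fusion of pathway members with overlapping windows.

    ``genes`` must already carry the +/-window extension.  Every pathway gene
    present in ``genes`` ends up in exactly one meta-gene; singletons become
    one-member meta-genes.  Member order inside a meta-gene and the order of
    meta-genes follow genomic coordinates, so the result is independent of
    the ordering of the GMT file.
    """
    members = sorted(
        (g for g in genes if g.gene_id in gene_set.gene_ids),
        key=lambda g: (g.chrom, g.start, g.end, g.gene_id),
    )
    out: list[MetaGene] = []
    for g in members:
        last = out[-1] if out else None
        if (
            last is not None
            and last.fused_window.chrom == g.chrom
            and g.start <= last.fused_window.end
        ):
            last.member_gene_ids.append(g.gene_id)
            last.fused_window = GeneWindow(
                last.fused_window.gene_id + "+" + g.gene_id,
                g.chrom,
                last.fused_window.start,
                max(last.fused_window.end, g.end),
                g.window_bp,
            )
        else:
            out.append(MetaGene([g.gene_id], g))
    return out


def pathway_enrichment(
    gene_pvals: Mapping[str, float],
    gene_set: GeneSet,
    meta_genes: list[MetaGene] | None = None,
    rescored: Mapping[str, float] | None = None,
) -> tuple[float | None, float | None, int]:
    """Rank-normalized chi-square sum over the pathway's (meta-)genes.

    ``gene_pvals`` is the genome-wide background of scored genes (gene id ->
    p).  When meta-genes are given, their members are removed from the
    background and replaced by the fused genes' re-computed p-values from
    ``rescored`` (meta id -> p).  The full background is qq-normalized, each
    pathway (meta-)gene's normalized p becomes a chi2_1 quantile, and the sum
    of the n quantiles is tested against chi2_n.

    Returns ``(p, statistic, n_meta_genes)``; ``(None, None, 0)`` marks a
    pathway with no scored genes (undefined score, not an error).
    """
    background = dict(gene_pvals)
    if meta_genes:
        if rescored is None:
            raise PathwayError("meta-gene fusion requires re-scored p-values")
        pathway_ids = []
        for mg in meta_genes:
            for gid in mg.member_gene_ids:
                background.pop(gid, None)
            if mg.meta_id in rescored and rescored[mg.meta_id] is not None:
                background[mg.meta_id] = float(rescored[mg.meta_id])
                pathway_ids.append(mg.meta_id)
    else:
        pathway_ids = [g for g in gene_set.gene_ids if g in background]
    if not pathway_ids:
        return None, None, 0
    ids = list(background)
    pvec = np.array([background[i] for i in ids], dtype=float)
    qq = qq_normalize(pvec)
    normalized = dict(zip(ids, qq))
    quantiles = np.array(
        [stats.chi2.isf(normalized[i], df=1) for i in sorted(pathway_ids)]
    )
    statistic = float(quantiles.sum())
    n = len(pathway_ids)
    return float(stats.chi2.sf(statistic, df=n)), statistic, n
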