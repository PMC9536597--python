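"""Model/Results interface over the gene-level cross-GWAS tests.

The classes here follow the fit-and-results convention of statistical
modelling packages: a model object is constructed from data (two harmonized
GWAS, a reference panel, a gene annotation), ``fit()`` runs the per-gene
tests and returns a results object holding the per-gene table, Bonferroni
thresholds and presentation helpers (``summary()``, ``to_tsv()``,
``qq_plot()``).

    >>> model = CoherenceModel.from_files("a.tsv", "b.tsv", "panel.tsv",
    ...                                   "genes.tsv")
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gwas_io, ldpanel, pathway, qform, ratio, scoring

logger = logging.getLogger(__name__)

__all__ = [
    "CoherenceModel", "CoherenceResults",
    "RatioModel", "RatioResults",
    "PathwayModel", "PathwayResults",
    "meta_combine",
]


class _GeneScanBase:
    """Shared plumbing: harmonized pair + panel + gene windows."""

    def __init__(
        self,
        pair: gwas_io.HarmonizedPair,
        panel: ldpanel.ReferencePanel,
        gene_windows: list[ldpanel.GeneWindow],
        accuracy: float = qform.DEFAULT_ACCURACY,
    ):
        if pair.w is None or pair.z is None:
            raise ValueError("pair must be score-transformed (transform_scores)")
        self.pair = pair
        self.panel = panel
        self.gene_windows = gene_windows
        self.accuracy = accuracy
        tab = pair.table
        self._chrom = tab["chrom"].to_numpy(dtype="U")
        self._pos = tab["pos"].to_numpy(dtype=np.int64)
        self._snp_ids = np.asarray(tab["snp_id"], dtype=object)

    @classmethod
    def from_files(
        cls,
        gwas_a,
        gwas_b,
        panel_path,
        annotation_path,
        column_map_a=None,
        column_map_b=None,
        panel_format: str = "matrix",
        window_bp: int = ldpanel.DEFAULT_WINDOW_BP,
        normalization: str = "qq",
        cutoff: float = 1e-16,
        allele_policy: str = "strict",
        **kwargs,
    ):
        a = gwas_io.read_summary_stats(gwas_a, column_map_a)
        b = gwas_io.read_summary_stats(gwas_b, column_map_b)
        pair = gwas_io.harmonize_pair(a, b, allele_policy)
        pair = gwas_io.transform_scores(pair, normalization, cutoff)
        panel = ldpanel.load_panel(panel_path, panel_format)
        windows = ldpanel.read_gene_annotation(annotation_path, window_bp)
        return cls(pair, panel, windows, **kwargs)

    def _gene_scores(self, windows: list[ldpanel.GeneWindow]):
        """(struct, w, z) restricted to the union of the windows, or None.

        SNP membership is decided on the GWAS coordinates; the correlation
        structure may drop panel-absent or monomorphic SNPs, and the score
        vectors follow its retained SNP list.
        """
        mask = np.zeros(self._pos.size, dtype=bool)
        for gw in windows:
            mask |= (
                (self._chrom == gw.chrom)
                & (self._pos >= gw.start)
                & (self._pos <= gw.end)
            )
        if not mask.any():
            return None
        ids = list(self._snp_ids[mask])
        try:
            struct = ldpanel.correlation_matrix(self.panel, ids)
        except ldpanel.PanelError:
            return None
        keep = [ids.index(s) for s in struct.snp_ids]
        sel = np.flatnonzero(mask)[keep]
        return struct, self.pair.w[sel], self.pair.z[sel]


class CoherenceModel(_GeneScanBase):
    """Gene-level coherence scan of two GWAS (the cross-scoring test).

    For every annotated gene with at least one shared SNP, tests the index
    I = w'z against the eigenvalue-weighted signed chi-square null, and
    reports per-trait enrichment and direction (D) tests alongside.
    """

    def fit(self, variance_mode: str = "exact_sum") -> "CoherenceResults":
        rows = []
        for gw in self.gene_windows:
            got = self._gene_scores([gw])
            if got is None:
                continue
            struct, w, z = got
            res = scoring.coherence_test(w, z, struct, gw.gene_id, self.accuracy)
            p_enr_a = scoring.enrichment_test(w, struct, self.accuracy)
            p_enr_b = scoring.enrichment_test(z, struct, self.accuracy)
            D_a, pDr_a, pDl_a = scoring.d_test(w, struct, variance_mode)
            D_b, pDr_b, pDl_b = scoring.d_test(z, struct, variance_mode)
            rows.append(
                {
                    "gene_id": gw.gene_id,
                    "chrom": gw.chrom,
                    "n_snps": struct.n_snps,
                    "I": res.index_I,
                    "p_coherent": res.p_coherent,
                    "p_anticoherent": res.p_anticoherent,
                    "p_enrich_a": p_enr_a,
                    "p_enrich_b": p_enr_b,
                    "D_a": D_a,
                    "p_D_right_a": pDr_a,
                    "p_D_left_a": pDl_a,
                    "D_b": D_b,
                    "p_D_right_b": pDr_b,
                    "p_D_left_b": pDl_b,
                }
            )
        table = pd.DataFrame(rows)
        return CoherenceResults(self, table)

    def score_meta_gene(self, meta: pathway.MetaGene, tail: str = "coherent"):
        """Re-computed coherence p on the union of a meta-gene's SNP windows."""
        windows = [
            gw for gw in self.gene_windows if gw.gene_id in meta.member_gene_ids
        ]
        got = self._gene_scores(windows)
        if got is None:
            return None
        struct, w, z = got
        res = scoring.coherence_test(w, z, struct, meta.meta_id, self.accuracy)
        return res.p_coherent if tail == "coherent" else res.p_anticoherent


@dataclass
class CoherenceResults:
    model: CoherenceModel
    table: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def bonferroni(self, n_trait_pairs: int = 1, alpha: float = 0.05) -> float:
        return scoring.bonferroni_threshold(max(self.n_genes, 1), n_trait_pairs, alpha)

    def gene_pvalues(self, tail: str = "coherent") -> dict[str, float]:
        col = "p_coherent" if tail == "coherent" else "p_anticoherent"
        return dict(zip(self.table["gene_id"], self.table[col]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self, n_trait_pairs: int = 1, top: int = 10) -> str:
        thr = self.bonferroni(n_trait_pairs)
        lines = [
            "Cross-GWAS gene coherence scan",
            "=" * 46,
            f"genes tested           {self.n_genes}",
            f"shared SNPs            {self.model.pair.n_shared}",
            f"normalization          {self.model.pair.normalization}",
            f"Bonferroni threshold   {thr:.3e}"
            f"  (0.05 / {self.n_genes} genes / {n_trait_pairs} trait pairs)",
            "",
        ]
        if self.n_genes:
            best = self.table.assign(
                p_min=self.table[["p_coherent", "p_anticoherent"]].min(axis=1)
            ).nsmallest(top, "p_min")
            lines.append(f"{'gene':<14}{'n_snps':>7}{'I':>12}"
                         f"{'p_coherent':>14}{'p_anticoherent':>16}")
            for r in best.itertuples():
                lines.append(
                    f"{r.gene_id:<14}{r.n_snps:>7}{r.I:>12.4g}"
                    f"{r.p_coherent:>14.4g}{r.p_anticoherent:>16.4g}"
                )
        return "\n".join(lines)

    def qq_plot(self, tail: str = "coherent", path=None):
        """QQ-plot of the observed gene p-values against the uniform."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        col = "p_coherent" if tail == "coherent" else "p_anticoherent"
        obs = np.sort(self.table[col].to_numpy())
        n = obs.size
        exp = (np.arange(n) + 0.5) / n
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(-np.log10(exp), -np.log10(obs), ".", ms=4)
        lim = max(1.0, -np.log10(obs.min()) if n else 1.0)
        ax.plot([0, lim], [0, lim], "--", color="gray", lw=1)
        ax.set_xlabel(r"expected $-\log_{10} p$")
        ax.set_ylabel(r"observed $-\log_{10} p$")
        ax.set_title(f"gene {tail} p-values")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


class RatioModel(_GeneScanBase):
    """Gene-level ratio (causal-direction) scan.

    GWAS ``a`` is the exposure (numerator scores w) and GWAS ``b`` the
    outcome (denominator scores z); R = w'z / z'z is not symmetric under
    swapping the two.
    """

    def __init__(self, *args, exposure_id="exposure", outcome_id="outcome",
                 **kwargs):
        super().__init__(*args, **kwargs)
        self.exposure_id = exposure_id
        self.outcome_id = outcome_id

    def fit(self) -> "RatioResults":
        rows = []
        for gw in self.gene_windows:
            got = self._gene_scores([gw])
            if got is None:
                continue
            struct, w, z = got
            if float(z @ z) == 0.0:
                continue
            res = ratio.ratio_test(
                w, z, struct, gw.gene_id, self.exposure_id, self.outcome_id,
                self.accuracy,
            )
            rows.append(
                {
                    "gene_id": gw.gene_id,
                    "chrom": gw.chrom,
                    "exposure": res.exposure_id,
                    "outcome": res.outcome_id,
                    "n_snps": res.n_snps,
                    "r": res.r,
                    "p_left": res.p_left,
                    "p_right": res.p_right,
                    "p_V_exposure": res.p_enrich_exposure,
                    "p_V_outcome": res.p_enrich_outcome,
                }
            )
        return RatioResults(self, pd.DataFrame(rows))


@dataclass
class RatioResults:
    model: RatioModel
    table: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def screen(self, alpha_R: float | None = None, alpha_V: float | None = None,
               n_trait_pairs: int = 1) -> pd.DataFrame:
        """Causal-candidate screen; defaults are Bonferroni thresholds.

        alpha_R defaults to 0.05 / (genes x 2 tail directions x trait pairs)
        and alpha_V to 0.05 / genes.  Adds screen_pass/screen_tail columns and
        returns the annotated table.
        """
        n = max(self.n_genes, 1)
        if alpha_R is None:
            alpha_R = 0.05 / (n * 2 * n_trait_pairs)
        if alpha_V is None:
            alpha_V = 0.05 / n
        t = self.table
        p_min = t[["p_left", "p_right"]].min(axis=1)
        t["screen_pass"] = (
            (p_min <= alpha_R)
            & (t["p_V_exposure"] <= alpha_V)
            & (t["p_V_outcome"] > alpha_V)
        )
        t["screen_tail"] = np.where(t["p_right"] <= t["p_left"], "right", "left")
        return t

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self, top: int = 10) -> str:
        lines = [
            f"Gene-wise ratio test: exposure={self.model.exposure_id} "
            f"outcome={self.model.outcome_id}",
            "=" * 56,
            f"genes tested  {self.n_genes}",
            "",
        ]
        if self.n_genes:
            best = self.table.assign(
                p_min=self.table[["p_left", "p_right"]].min(axis=1)
            ).nsmallest(top, "p_min")
            lines.append(f"{'gene':<14}{'r':>10}{'p_left':>12}{'p_right':>12}"
                         f"{'p_V_exp':>12}{'p_V_out':>12}")
            for row in best.itertuples():
                lines.append(
                    f"{row.gene_id:<14}{row.r:>10.4g}{row.p_left:>12.4g}"
                    f"{row.p_right:>12.4g}{row.p_V_exposure:>12.4g}"
                    f"{row.p_V_outcome:>12.4g}"
                )
        return "\n".join(lines)


class PathwayModel:
    """Gene-set scoring of gene-level p-values with meta-gene fusion.

    ``gene_pvals`` is the genome-wide background (gene id -> p).  When a
    fitted :class:`CoherenceModel` is supplied, pathway members with
    overlapping extended windows are fused and re-scored on their SNP union;
    otherwise genes enter individually.
    """

    def __init__(
        self,
        gene_pvals: dict[str, float],
        gene_sets: list[pathway.GeneSet],
        coherence_model: CoherenceModel | None = None,
        tail: str = "coherent",
    ):
        self.gene_pvals = dict(gene_pvals)
        self.gene_sets = gene_sets
        self.coherence_model = coherence_model
        self.tail = tail

    def fit(self) -> "PathwayResults":
        rows = []
        for gs in self.gene_sets:
            meta = None
            rescored = None
            if self.coherence_model is not None:
                windows = [
                    gw for gw in self.coherence_model.gene_windows
                    if gw.gene_id in self.gene_pvals
                ]
                meta = pathway.fuse_meta_genes(windows, gs)
                rescored = {
                    mg.meta_id: self.coherence_model.score_meta_gene(mg, self.tail)
                    for mg in meta
                }
            p, stat, n = pathway.pathway_enrichment(
                self.gene_pvals, gs, meta, rescored
            )
            rows.append(
                {"pathway": gs.name, "n_meta_genes": n, "statistic": stat, "p": p}
            )
        return PathwayResults(self, pd.DataFrame(rows))


@dataclass
class PathwayResults:
    model: PathwayModel
    table: pd.DataFrame

    def bonferroni(self, n_traits: int = 1, alpha: float = 0.05) -> float:
        return scoring.bonferroni_threshold(max(len(self.table), 1), n_traits, alpha)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self, top: int = 10) -> str:
        lines = [
            "Pathway enrichment of gene scores",
            "=" * 40,
            f"gene sets tested  {len(self.table)}",
            f"Bonferroni        {self.bonferroni():.3e}",
            "",
        ]
        scored = self.table.dropna(subset=["p"])
        for row in scored.nsmallest(top, "p").itertuples():
            lines.append(f"{row.pathway:<36}{row.n_meta_genes:>4}  p={row.p:.4g}")
        return "\n".join(lines)


def meta_combine(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    gene_col: str = "gene_id",
    p_col: str = "p",
) -> pd.DataFrame:
    """Multiplicative meta-analysis of two per-gene score tables.

    Combines each shared gene's two enrichment p-values through the
    single-element product-normal (direction information is not available at
    this level).  Returns gene_id, p_a, p_b, p_combined.
    """
    merged = scores_a[[gene_col, p_col]].merge(
        scores_b[[gene_col, p_col]], on=gene_col, suffixes=("_a", "_b")
    )
    combined = [
        qform.combine_pvalues_product_normal(pa, pb, 1)
        for pa, pb in zip(merged[f"{p_col}_a"], merged[f"{p_col}_b"])
    ]
    merged["p_combined"] = combined
    return merged.rename(columns={f"{p_col}_a": "p_a", f"{p_col}_b": "p_b"})
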