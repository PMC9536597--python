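"""Gene-level tests: cross-GWAS coherence, single-trait enrichment, direction.

Let w and z be the signed SNP score vectors of a gene for two traits, both
distributed N(0, Sigma) under the null with Sigma the LD matrix of the gene
window.  The coherence index is the second cross-moment

    I = w'z,

whose null distribution is the signed chi-square mixture

    I  ~  sum_i  lambda_i/2 [chi2_1]  -  lambda_i/2 [chi2_1],

with lambda_i the retained eigenvalues of Sigma.  The right tail of I tests
for coherent (same-sign) SNP effects, the left tail for anti-coherent ones.
Setting w = z yields the classic LD-corrected enrichment statistic z'z with
the all-positive null sum_i lambda_i [chi2_1].  The D statistic sum_i z_i
establishes the base direction of the aggregated gene effect against its
normal null.

Note that w and z are deliberately *not* centered over the gene SNPs: the
test targets a non-vanishing second cross-moment, not a covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .ldpanel import CorrelationStructure
from .qform import DEFAULT_ACCURACY, ChiSquareMixture, mixture_tail

__all__ = ["GeneCoherenceResult", "coherence_test", "enrichment_test", "d_test",
           "bonferroni_threshold", "ScoringError"]


class ScoringError(ValueError):
    pass


@dataclass
class GeneCoherenceResult:
    gene_id: str
    n_snps: int
    index_I: float
    p_coherent: float
    p_anticoherent: float
    p_enrich_a: float | None = None
    p_enrich_b: float | None = None
    D_a: float | None = None
    p_D_right_a: float | None = None
    p_D_left_a: float | None = None
    D_b: float | None = None
    p_D_right_b: float | None = None
    p_D_left_b: float | None = None


def _check_dims(v: np.ndarray, struct: CorrelationStructure, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size != struct.n_snps:
        raise ScoringError(
            f"{name} has length {v.size}, correlation structure has "
            f"{struct.n_snps} SNPs"
        )
    return v


def coherence_null(struct: CorrelationStructure) -> ChiSquareMixture:
    """Signed mixture (+lambda_i/2, -lambda_i/2; 1 dof each) for I = w'z."""
    lam = struct.eigvals
    return ChiSquareMixture(
        np.concatenate([lam / 2.0, -lam / 2.0]), np.ones(2 * lam.size, dtype=int)
    )


def coherence_test(
    w: np.ndarray,
    z: np.ndarray,
    struct: CorrelationStructure,
    gene_id: str = "",
    accuracy: float = DEFAULT_ACCURACY,
) -> GeneCoherenceResult:
    """Test I = w'z against its LD-aware signed chi-square mixture null.

    Returns both tails; for a single SNP this reduces to the product-normal
    test.  Symmetric in w and z.
    """
    w = _check_dims(w, struct, "w")
    z = _check_dims(z, struct, "z")
    index = float(w @ z)
    mix = coherence_null(struct)
    right = mixture_tail(mix, index, "right", accuracy)
    left = mixture_tail(mix, index, "left", accuracy)
    return GeneCoherenceResult(
        gene_id=gene_id,
        n_snps=struct.n_snps,
        index_I=index,
        p_coherent=right.probability,
        p_anticoherent=left.probability,
    )


def enrichment_test(
    z: np.ndarray,
    struct: CorrelationStructure,
    accuracy: float = DEFAULT_ACCURACY,
) -> float:
    """LD-corrected gene enrichment: z'z against sum_i lambda_i [chi2_1]."""
    z = _check_dims(z, struct, "z")
    stat = float(z @ z)
    mix = ChiSquareMixture(struct.eigvals, np.ones(struct.eigvals.size, dtype=int))
    return mixture_tail(mix, stat, "right", accuracy).probability


def d_test(
    z: np.ndarray,
    struct: CorrelationStructure,
    variance_mode: Literal["exact_sum", "paper_frobenius"] = "exact_sum",
) -> tuple[float, float, float]:
    """Direction of the aggregated gene effect: D = sum_i z_i vs N(0, V).

    ``exact_sum`` uses V = 1'Sigma 1, the variance of a sum of jointly normal
    scores (computed on the regularized spectrum); ``paper_frobenius`` uses
    V = trace(Sigma) = |C|_F^2, provided as a compatibility mode.  Returns
    (D, right-tail p, left-tail p); a small right tail indicates a positive
    aggregated direction.
    """
    z = _check_dims(z, struct, "z")
    lam, U = struct.eigvals, struct.eigvecs
    if variance_mode == "exact_sum":
        proj = U.T @ np.ones(struct.n_snps)
        V = float(np.sum(lam * proj**2))
    elif variance_mode == "paper_frobenius":
        V = float(np.sum(lam))
    else:
        raise ScoringError(f"unknown variance_mode {variance_mode!r}")
    if V <= 0.0:
        raise ScoringError("degenerate D-test variance after regularization")
    D = float(np.sum(z))
    zscore = D / np.sqrt(V)
    return D, float(stats.norm.sf(zscore)), float(stats.norm.cdf(zscore))


def bonferroni_threshold(n_genes: int, n_traits: int = 1, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (n_genes * n_traits)."""
    if n_genes < 1 or n_traits < 1:
        raise ScoringError("counts must be positive")
    return alpha / (n_genes * n_traits)
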