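"""Gene-wise ratio test for causal direction between an exposure and an outcome.

The normalized index

    R = w'z / z'z

is the weighted-least-squares slope of the (decorrelated) exposure scores w
on the outcome scores z.  Under the null of independent N(0, Sigma) vectors

    Pr(R <= r) = F_{v z}(0),   v = w - r z  (decorrelated frame),

which is again a signed chi-square mixture: per retained eigenvalue lambda_i
of Sigma the coefficients are

    + lambda_i sqrt(1+r^2) (1+rho)/2   and   - lambda_i sqrt(1+r^2) (1-rho)/2

with rho = -r / sqrt(1+r^2), each with one degree of freedom, evaluated as a
left tail at the origin.  In one dimension R is Cauchy and the cdf reduces to
0.5 + arctan(r)/pi.

R is not symmetric in w and z: the trait supplying the denominator z'z is the
outcome.  A surviving causal candidate must additionally be enrichment-
significant for the exposure but not for the outcome (the screen).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ldpanel import CorrelationStructure
from .qform import DEFAULT_ACCURACY, ChiSquareMixture, mixture_tail
from .scoring import ScoringError, _check_dims, enrichment_test

__all__ = ["RatioResult", "ratio_cdf", "ratio_test", "causal_screen"]


@dataclass
class RatioResult:
    gene_id: str
    exposure_id: str
    outcome_id: str
    n_snps: int
    r: float
    p_right: float
    p_left: float
    p_enrich_exposure: float | None = None
    p_enrich_outcome: float | None = None
    screen_pass: bool | None = None
    screen_tail: str | None = None


def ratio_null(eigvals: np.ndarray, r: float) -> ChiSquareMixture:
    lam = np.asarray(eigvals, dtype=float)
    scale = np.sqrt(1.0 + r * r)
    rho = -r / scale
    pos = lam * scale * (1.0 + rho) / 2.0
    neg = -lam * scale * (1.0 - rho) / 2.0
    return ChiSquareMixture(np.concatenate([pos, neg]),
                            np.ones(2 * lam.size, dtype=int))


def ratio_cdf(r: float, eigvals: np.ndarray,
              accuracy: float = DEFAULT_ACCURACY) -> float:
    """Pr(R <= r) for the given retained eigenvalue spectrum."""
    eigvals = np.asarray(eigvals, dtype=float)
    if eigvals.size == 0:
        raise ScoringError("ratio_cdf needs at least one retained eigenvalue")
    return mixture_tail(ratio_null(eigvals, r), 0.0, "left", accuracy).probability


def ratio_test(
    w_exposure: np.ndarray,
    z_outcome: np.ndarray,
    struct: CorrelationStructure,
    gene_id: str = "",
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    accuracy: float = DEFAULT_ACCURACY,
    with_enrichment: bool = True,
) -> RatioResult:
    """Ratio test of exposure scores against outcome scores for one gene.

    The ratio r = w'z / z'z is computed on the original (not decorrelated)
    vectors; the two are equal because the rotation into the eigenbasis is
    orthogonal.
    """
    w = _check_dims(w_exposure, struct, "w_exposure")
    z = _check_dims(z_outcome, struct, "z_outcome")
    denom = float(z @ z)
    if denom == 0.0:
        raise ScoringError(f"gene {gene_id or '<unnamed>'}: outcome scores are "
                           "all zero (degenerate denominator)")
    r = float(w @ z) / denom
    mix = ratio_null(struct.eigvals, r)
    # Pr(R <= r) = Pr(vz <= 0) and Pr(R > r) = Pr(vz > 0): evaluate each tail
    # directly so extreme p-values keep relative accuracy
    res = RatioResult(
        gene_id=gene_id,
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        n_snps=struct.n_snps,
        r=r,
        p_right=mixture_tail(mix, 0.0, "right", accuracy).probability,
        p_left=mixture_tail(mix, 0.0, "left", accuracy).probability,
    )
    if with_enrichment:
        res.p_enrich_exposure = enrichment_test(w, struct, accuracy)
        res.p_enrich_outcome = enrichment_test(z, struct, accuracy)
    return res


def causal_screen(
    results: list[RatioResult],
    alpha_R: float,
    alpha_V: float,
) -> list[RatioResult]:
    """Filter ratio results to causal candidates.

    A gene survives when its ratio tail is significant (min of the two
    one-sided p-values <= alpha_R), the exposure is enrichment-significant
    (p_V <= alpha_V) and the outcome is not (p_V > alpha_V); the surviving
    tail direction is annotated.  Potential confounders are not evaluated
    here and must be excluded by other means.
    """
    out = []
    for res in results:
        if res.p_enrich_exposure is None or res.p_enrich_outcome is None:
            raise ScoringError(
                f"gene {res.gene_id}: causal_screen needs enrichment p-values"
            )
        p_min = min(res.p_right, res.p_left)
        keep = (
            p_min <= alpha_R
            and res.p_enrich_exposure <= alpha_V
            and res.p_enrich_outcome > alpha_V
        )
        res.screen_pass = keep
        res.screen_tail = ("right" if res.p_right <= res.p_left else "left")
        if keep:
            out.append(res)
    return out
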