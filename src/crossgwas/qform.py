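"""Tail probabilities of signed linear combinations of central chi-square variables.

The statistic at the heart of every test in this package is a quadratic (or
bilinear) form in jointly normal variables.  After decorrelation such a form
is distributed as

    Xi = sum_i a_i [chi2_{n_i}],

a linear combination of independent central chi-square variables with real
(possibly negative) coefficients ``a_i`` and degrees of freedom ``n_i``.  No
closed form for the cdf of Xi exists in general; this module computes it
numerically along three complementary routes:

* characteristic-function inversion (Davies' approach, via Imhof's explicit
  form of the inversion integral) -- the fast first attempt;
* Ruben's series combined with a gamma convolution of the positive and
  negative parts of the mixture -- a positive-integrand representation whose
  *relative* accuracy survives arbitrarily deep tails, used whenever the
  inversion integral cannot certify the requested accuracy; evaluated in
  double precision, with an arbitrary-precision (mpmath) variant beneath the
  double-precision floor;
* a saddlepoint-tilted contour inversion for spectra too widely spread for
  Ruben's series to converge.

The product of two standard normals with correlation ``rho`` is the special
two-component case

    z*w ~ (1+rho)/2 [chi2_1] - (1-rho)/2 [chi2_1],

which powers the single-SNP coherence test and the multiplicative
meta-analysis of per-trait gene scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import mpmath as mp
import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "ChiSquareMixture",
    "TailResult",
    "mixture_tail",
    "product_normal_tail",
    "combine_pvalues_product_normal",
    "fisher_combine",
    "QFormError",
    "NumericalFailure",
]

#: default requested absolute accuracy for tail probabilities
DEFAULT_ACCURACY = 1e-12

#: probabilities below ESCALATE_FACTOR * accuracy are recomputed on the
#: positive-integrand route so small p-values keep relative accuracy
ESCALATE_FACTOR = 100.0

#: decimal digits for the arbitrary-precision (sub-double-floor) variant
HIGH_PRECISION_DPS = 50


class QFormError(ValueError):
    """Invalid mixture or parameter."""


class NumericalFailure(RuntimeError):
    """All numerical routes failed to reach a usable result."""


class _SlowSeries(RuntimeError):
    """Ruben's series would need too many terms (wide coefficient spread)."""


@dataclass(frozen=True)
class ChiSquareMixture:
    """A linear combination ``sum_i coeffs[i] * chi2(dofs[i])``.

    Zero-coefficient terms are removed and terms with equal coefficients are
    merged (their degrees of freedom add) on construction.
    """

    coeffs: tuple[float, ...]
    dofs: tuple[int, ...]

    def __init__(self, coeffs: Sequence[float], dofs: Sequence[int]):
        coeffs = [float(a) for a in coeffs]
        dofs = [int(n) for n in dofs]
        if len(coeffs) != len(dofs):
            raise QFormError("coeffs and dofs must have equal length")
        if any(n < 1 for n in dofs):
            raise QFormError("degrees of freedom must be >= 1")
        merged: dict[float, int] = {}
        for a, n in zip(coeffs, dofs):
            if a == 0.0:
                continue
            merged[a] = merged.get(a, 0) + n
        if not merged:
            raise QFormError("mixture has no nonzero coefficients")
        items = sorted(merged.items(), key=lambda t: -t[0])
        object.__setattr__(self, "coeffs", tuple(a for a, _ in items))
        object.__setattr__(self, "dofs", tuple(n for _, n in items))

    def negated(self) -> "ChiSquareMixture":
        return ChiSquareMixture([-a for a in self.coeffs], self.dofs)

    @property
    def total_dof(self) -> int:
        return int(sum(self.dofs))

    @property
    def mean(self) -> float:
        return float(sum(a * n for a, n in zip(self.coeffs, self.dofs)))

    def split(self):
        """((pos_coeffs, pos_dofs), (neg_coeffs_as_positive, neg_dofs))."""
        pos = [(a, n) for a, n in zip(self.coeffs, self.dofs) if a > 0]
        neg = [(-a, n) for a, n in zip(self.coeffs, self.dofs) if a < 0]
        return pos, neg

    def sample(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Draw realizations of the mixture (used by the Monte-Carlo route)."""
        out = np.zeros(n_draws)
        for a, n in zip(self.coeffs, self.dofs):
            out += a * rng.chisquare(n, n_draws)
        return out


@dataclass(frozen=True)
class TailResult:
    probability: float
    achieved_accuracy: float
    method: Literal["davies", "ruben", "high_precision", "monte_carlo"]


# ---------------------------------------------------------------------------
# route 1: characteristic-function inversion (Imhof's integrand, QUADPACK)
# ---------------------------------------------------------------------------

def _imhof_right_tail(mix: ChiSquareMixture, x: float):
    """P(Xi > x) via the inversion integral, with QUADPACK's error estimate.

    P(Xi > x) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * rho(u)) du
    theta(u)  = 1/2 sum_i n_i atan(a_i u) - x u / 2
    rho(u)    = prod_i (1 + a_i^2 u^2)^(n_i / 4)
    """
    a = np.asarray(mix.coeffs)
    n = np.asarray(mix.dofs, dtype=float)
    slope0 = 0.5 * float(np.sum(n * a)) - 0.5 * x

    def integrand(u: float) -> float:
        if u == 0.0:
            return slope0
        theta = 0.5 * np.sum(n * np.arctan(a * u)) - 0.5 * x * u
        log_rho = 0.25 * np.sum(n * np.log1p((a * u) ** 2))
        if log_rho > 700.0:  # exp overflow; integrand is 0 to double precision
            return 0.0
        return float(np.sin(theta) / (u * np.exp(log_rho)))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(integrand, 0.0, np.inf,
                                  epsabs=1e-14 * np.pi, epsrel=1e-13, limit=400)
    return 0.5 + val / np.pi, err / np.pi


# ---------------------------------------------------------------------------
# route 2: Ruben's series + gamma convolution (positive integrand)
# ---------------------------------------------------------------------------

def _ruben_terms_needed(coeffs, log_tol: float) -> int:
    """Estimated series length for convergence to exp(-log_tol)."""
    q = 1.0 - float(min(coeffs)) / float(max(coeffs))
    if q <= 0.0:
        return 1
    return int(log_tol / -np.log(q)) + 1


def _ruben_coeffs_float(coeffs, dofs, max_terms: int, decay_tol: float = 1e-40):
    """Ruben mixing weights c_k (nonnegative, summing to one) in doubles.

    F(x) = sum_k c_k F_{chi2(nu + 2k)}(x / beta) with beta = min coefficient.
    The series is truncated once the weights have decayed to ``decay_tol``
    times their maximum; the geometric decay of the remaining mass then keeps
    the truncation negligible relative to any representable tail value.
    """
    beta = float(min(coeffs))
    ratios = np.array([1.0 - beta / a for a in coeffs])
    dn = np.array(dofs, dtype=float)
    c0 = float(np.prod((beta / np.asarray(coeffs, dtype=float)) ** (dn / 2.0)))
    cs = [c0]
    gs: list[float] = []
    powers = np.ones_like(ratios)
    cmax = c0
    for k in range(1, max_terms):
        powers *= ratios
        gs.append(0.5 * float(np.sum(dn * powers)))
        ck = float(np.dot(gs[::-1], cs)) / k
        cs.append(ck)
        cmax = max(cmax, ck)
        if ck < decay_tol * cmax and k > 4:
            break
    else:
        raise _SlowSeries("Ruben's series did not converge in double precision")
    return beta, np.asarray(cs), max(1.0 - float(np.sum(cs)), 0.0)


class _PositivePartFloat:
    """Survival/cdf/density of an all-positive mixture via Ruben's series.

    Consecutive series terms obey Q(s+1, t) = Q(s, t) + t^s e^-t / s!, so the
    chi-square cdfs of all orders come from one incomplete-gamma evaluation
    plus a vectorized cumulative recursion.
    """

    def __init__(self, coeffs, dofs, max_terms: int = 4000):
        if _ruben_terms_needed(coeffs, 95.0) > max_terms:
            raise _SlowSeries("coefficient spread too wide for Ruben's series")
        self.coeffs = [float(a) for a in coeffs]
        self.dofs = list(dofs)
        self.beta, self.cs, self.trunc = _ruben_coeffs_float(
            coeffs, dofs, max_terms
        )
        self.nu = int(sum(dofs))
        self.mean = float(sum(a * n for a, n in zip(coeffs, dofs)))
        k = np.arange(self.cs.size)
        h0 = self.nu / 2.0
        self._log_gamma_cum = np.concatenate(
            [[0.0], np.cumsum(np.log(h0 + 1.0 + k[:-1]))]
        )

    def _terms(self, x: float) -> tuple[float, np.ndarray]:
        """(t, T) with T_k = t^(h0+k) e^-t / Gamma(h0+k+1)."""
        t = x / (2.0 * self.beta)
        h0 = self.nu / 2.0
        k = np.arange(self.cs.size)
        logT = (h0 + k) * np.log(t) - t - special.gammaln(h0 + 1.0) \
            - self._log_gamma_cum
        return t, np.exp(logT)

    def sf(self, x: float) -> float:
        if x <= 0.0:
            return 1.0
        t, T = self._terms(x)
        q0 = special.gammaincc(self.nu / 2.0, t)
        q = q0 + np.concatenate([[0.0], np.cumsum(T[:-1])])
        return float(np.dot(self.cs, q))

    def cdf(self, x: float) -> float:
        if x <= 0.0:
            return 0.0
        t, T = self._terms(x)
        p0 = special.gammainc(self.nu / 2.0, t)
        p = np.maximum(p0 - np.concatenate([[0.0], np.cumsum(T[:-1])]), 0.0)
        return float(np.dot(self.cs, p))

    def pdf(self, x: float) -> float:
        if x <= 0.0:
            return 0.0
        t, T = self._terms(x)
        h0 = self.nu / 2.0
        k = np.arange(self.cs.size)
        # chi2 density at dof nu+2k in t-units: T_k * (h0+k) / t / (2 beta)
        dens = T * (h0 + k) / t / (2.0 * self.beta)
        return float(np.dot(self.cs, dens))

    def chernoff_cut(self, log_tol: float) -> float:
        """b with S(b) provably below exp(-log_tol)."""
        s = 1.0 / (4.0 * max(self.coeffs))
        Ks = -0.5 * float(
            sum(n * np.log1p(-2.0 * a * s) for a, n in zip(self.coeffs, self.dofs))
        )
        return (Ks + log_tol) / s


def _convolution_right_tail_float(mix: ChiSquareMixture, x: float):
    """P(Xi > x) = E_B[S_A(x + B)] with Xi = A - B, in double precision.

    The integrand is nonnegative, so the result keeps relative accuracy down
    to the double-precision floor.  Raises _SlowSeries when either part's
    Ruben series would converge too slowly.
    """
    pos, neg = mix.split()
    if not neg:
        A = _PositivePartFloat([a for a, _ in pos], [n for _, n in pos])
        return A.sf(x), max(abs(A.sf(x)) * 1e-12, A.trunc)
    if not pos:
        B = _PositivePartFloat([a for a, _ in neg], [n for _, n in neg])
        val = B.cdf(-x) if x < 0 else 0.0
        return val, max(abs(val) * 1e-12, B.trunc)
    A = _PositivePartFloat([a for a, _ in pos], [n for _, n in pos])
    B = _PositivePartFloat([a for a, _ in neg], [n for _, n in neg])
    lo = 0.0 if x >= 0 else -x
    hi = lo + B.chernoff_cut(46.0)  # S_B beyond < 1e-20
    scale = max(B.mean, 1e-8)
    pts = sorted({lo, min(lo + scale, hi), min(lo + 8 * scale, hi),
                  min(lo + 40 * scale, hi), hi})
    total = 0.0
    err = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        for a_, b_ in zip(pts[:-1], pts[1:]):
            v, e = integrate.quad(lambda b: A.sf(x + b) * B.pdf(b), a_, b_,
                                  epsabs=1e-300, epsrel=1e-12, limit=200)
            total += v
            err += e
    if x < 0:
        total += B.cdf(-x)  # region where S_A(x + b) == 1
    return total, max(err, total * 1e-12, A.trunc + B.trunc)


def _convolution_right_tail_mp(mix: ChiSquareMixture, x: float, dps: int):
    """Arbitrary-precision variant, for results below the double floor."""
    with mp.workdps(dps):
        pos, neg = mix.split()
        if not neg or not pos:
            raise _SlowSeries("single-signed handled in double precision")
        A = _PositivePartFloat([a for a, _ in pos], [n for _, n in pos])
        B = _PositivePartFloat([a for a, _ in neg], [n for _, n in neg])

        def sf_mp(part, y):
            # direct mpmath series evaluation using the double-precision c_k
            if y <= 0:
                return mp.mpf(1)
            t = mp.mpf(y) / (2 * part.beta)
            h0 = mp.mpf(part.nu) / 2
            T = mp.e ** (h0 * mp.log(t) - t - mp.loggamma(h0 + 1))
            g = mp.gammainc(h0, t, mp.inf, regularized=True)
            out = mp.mpf(0)
            for k, c in enumerate(part.cs):
                out += mp.mpf(float(c)) * g
                g += T
                T *= t / (h0 + k + 1)
            return out

        def pdf_mp(part, y):
            if y <= 0:
                return mp.mpf(0)
            t = mp.mpf(y) / (2 * part.beta)
            h0 = mp.mpf(part.nu) / 2
            d = mp.e ** ((h0 - 1) * mp.log(t) - t - mp.loggamma(h0))
            out = mp.mpf(0)
            for k, c in enumerate(part.cs):
                out += mp.mpf(float(c)) * d
                d *= t / (h0 + k)
            return out / (2 * part.beta)

        lo = mp.mpf(0) if x >= 0 else mp.mpf(-x)
        hi = lo + mp.mpf(B.chernoff_cut(float(dps * 2.4 + 20)))
        scale = mp.mpf(max(B.mean, 1e-8))
        pts = sorted({lo, min(lo + scale, hi), min(lo + 8 * scale, hi),
                      min(lo + 40 * scale, hi), hi})
        val = mp.quad(lambda b: sf_mp(A, mp.mpf(x) + b) * pdf_mp(B, b), pts)
        if x < 0:
            val += 1 - sf_mp(B, -mp.mpf(x))
        return val


# ---------------------------------------------------------------------------
# route 3: saddlepoint-tilted contour inversion (any coefficient spread)
# ---------------------------------------------------------------------------

def _tilted_right_tail(mix: ChiSquareMixture, x: float):
    """P(Xi > x) for x above the mean via saddlepoint-tilted inversion.

    P(Xi > x) = (1/pi) int_0^T Re[ exp(K(s0+it) - (s0+it)x) / (s0+it) ] dt,
    where K is the cumulant generating function and s0 > 0 solves K'(s0) = x
    (the integrand is even in t).  On the tilted contour the integrand peaks
    at t = 0 with magnitude of the order of the result, so small tails keep
    ~1e-9 relative accuracy in double precision for any coefficient spread.
    """
    a = np.asarray(mix.coeffs)
    n = np.asarray(mix.dofs, dtype=float)
    pos = a[a > 0]

    def K1(s):
        return float(np.sum(n * a / (1.0 - 2.0 * a * s)))

    s_hi = float(1.0 / (2.0 * pos.max())) if pos.size else np.inf
    if np.isinf(s_hi):
        hi = 1.0
        while K1(hi) < x:
            hi *= 2.0
    else:
        hi = s_hi * (1.0 - 1e-14)
    from scipy.optimize import brentq

    s0 = brentq(lambda s: K1(s) - x, 0.0, hi, xtol=1e-300, rtol=1e-15)
    K_s0 = float(-np.sum(n / 2.0 * np.log1p(-2.0 * a * s0)))
    K2_s0 = float(np.sum(2.0 * n * a**2 / (1.0 - 2.0 * a * s0) ** 2))
    sigma = 1.0 / np.sqrt(K2_s0)
    base = K_s0 - s0 * x

    def g(t):
        s = complex(s0, t)
        Ks = -0.5 * np.sum(n * np.log(1.0 - 2.0 * a * s))
        return (np.exp(Ks - s * x - base) / s).real

    def log_envelope(t):
        return float(
            -0.25 * np.sum(n * np.log((1.0 - 2.0 * a * s0) ** 2 + (2.0 * a * t) ** 2))
            - 0.5 * np.log(s0**2 + t**2)
        )

    # truncate where the envelope bound is negligible vs the Gaussian main lobe
    target = np.log(np.sqrt(2.0 * np.pi) * sigma) - 16.0 * np.log(10.0)
    T = 8.0 * sigma
    while log_envelope(T) + np.log(2.0 * T) > target and T < sigma * 1e12:
        T *= 2.0
    total = 0.0
    err = 0.0
    lo_t, hi_t = 0.0, 8.0 * sigma
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        while lo_t < T:
            hi_t = min(hi_t, T)
            v, e = integrate.quad(g, lo_t, hi_t, epsabs=1e-15, epsrel=1e-12,
                                  limit=400)
            total += v
            err += e
            lo_t, hi_t = hi_t, hi_t * 4.0
    p = np.exp(base) * max(total, 0.0) / np.pi
    return p, max(np.exp(base) * err / np.pi, p * 1e-9)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _positive_route_right_tail(mix: ChiSquareMixture, x: float, dps: int):
    """Best small-tail route: convolution, then tilted; complement for the
    large side so both keep relative accuracy.  Returns (p, err, method)."""
    small_side = x >= mix.mean
    work = mix if small_side else mix.negated()
    xw = x if small_side else -x
    try:
        p, err = _convolution_right_tail_float(work, xw)
        method = "ruben"
        if p == 0.0 and xw < _support_sup(work):
            p = float(_convolution_right_tail_mp(work, xw, dps))
            err = max(p * 1e-10, 5e-324)
            method = "high_precision"
    except _SlowSeries:
        has_pos = any(c > 0 for c in work.coeffs)
        sd = np.sqrt(2.0 * sum(a * a * n for a, n in zip(work.coeffs, work.dofs)))
        if not has_pos and xw >= 0:
            p, err = 0.0, 0.0
        elif xw > work.mean + 0.5 * sd:
            p, err = _tilted_right_tail(work, xw)
        else:
            # too close to the mean for a stable saddlepoint tilt (the 1/s
            # factor degenerates); the inversion integral is accurate here
            p, err = _imhof_right_tail(work, xw)
        method = "high_precision"
    if not small_side:
        p, err = 1.0 - p, err
    return p, err, method


def _support_sup(mix: ChiSquareMixture) -> float:
    return np.inf if any(c > 0 for c in mix.coeffs) else 0.0


def mixture_tail(
    mix: ChiSquareMixture,
    x: float,
    tail: Literal["left", "right"] = "right",
    accuracy: float = DEFAULT_ACCURACY,
    method: Literal["auto", "davies", "high_precision", "monte_carlo"] = "auto",
    dps: int = HIGH_PRECISION_DPS,
    n_draws: int = 10**6,
    seed: int | None = None,
) -> TailResult:
    """Tail probability of a signed chi-square mixture at ``x``.

    Parameters
    ----------
    mix : ChiSquareMixture
    x : evaluation point.
    tail : ``"right"`` returns ``P(Xi > x)``, ``"left"`` returns ``P(Xi <= x)``.
    accuracy : requested absolute accuracy (> 0).
    method : ``"auto"`` runs the characteristic-function inversion and
        escalates to the positive-integrand (Ruben convolution / tilted
        contour) routes when the result is smaller than 100x the requested
        accuracy or the quadrature error estimate is too large; the other
        values force a specific route.
    dps : decimal digits for the arbitrary-precision variant (results below
        the double-precision floor).
    n_draws, seed : Monte-Carlo route only.

    Probabilities are clamped to [0, 1]; a vanishing tail inside the support
    is recomputed in arbitrary precision rather than reported as 0.
    """
    if accuracy <= 0:
        raise QFormError("accuracy must be > 0")
    if tail not in ("left", "right"):
        raise QFormError(f"unknown tail {tail!r}")
    # left tail of Xi at x == right tail of -Xi at -x (continuous distribution)
    work = mix if tail == "right" else mix.negated()
    xw = x if tail == "right" else -x

    # a single scaled chi-square needs no inversion at all
    if len(work.coeffs) == 1 and method != "monte_carlo":
        a, n = work.coeffs[0], work.dofs[0]
        p = float(stats.chi2.sf(xw / a, n)) if a > 0 \
            else float(stats.chi2.cdf(xw / a, n))
        return TailResult(p, min(accuracy, max(abs(p) * 1e-14, 5e-324)), "ruben")

    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        draws = work.sample(n_draws, rng)
        p = float(np.mean(draws > xw))
        se = float(np.sqrt(max(p * (1 - p), 1.0 / n_draws) / n_draws))
        return TailResult(p, se, "monte_carlo")

    if method in ("auto", "davies"):
        try:
            p, err = _imhof_right_tail(work, xw)
        except Exception:
            p, err = np.nan, np.inf
        clean = np.isfinite(p) and -1e-8 <= p <= 1 + 1e-8
        if method == "davies":
            if not clean:
                raise NumericalFailure(
                    f"characteristic-function inversion failed for {work} at x={xw}"
                )
            return TailResult(min(max(p, 0.0), 1.0), max(err, 1e-16), "davies")
        if clean and err <= accuracy and p >= ESCALATE_FACTOR * accuracy:
            return TailResult(min(max(p, 0.0), 1.0), max(err, 1e-16), "davies")

    try:
        p, err, used = _positive_route_right_tail(work, xw, dps)
    except Exception as exc:  # pragma: no cover - defensive
        raise NumericalFailure(
            f"tail computation failed for {work} at x={xw}: {exc}"
        ) from exc
    if method == "high_precision":
        used = "high_precision"
    return TailResult(min(max(p, 0.0), 1.0), max(err, 5e-324), used)


def product_normal_tail(
    x: float,
    rho: float,
    tail: Literal["left", "right"] = "right",
    accuracy: float = DEFAULT_ACCURACY,
    **kwargs,
) -> TailResult:
    """Tail probability of the product of two standard normals with correlation rho.

    Uses the chi-square mixture representation
    ``z*w ~ (1+rho)/2 [chi2_1] - (1-rho)/2 [chi2_1]``.
    """
    if not -1.0 < rho < 1.0:
        raise QFormError("rho must lie in (-1, 1)")
    mix = ChiSquareMixture([(1.0 + rho) / 2.0, -(1.0 - rho) / 2.0], [1, 1])
    return mixture_tail(mix, x, tail=tail, accuracy=accuracy, **kwargs)


def _p_to_z(p: float) -> float:
    """Two-sided p-value to score magnitude via the inverse chi2_1 cdf."""
    if not 0.0 < p <= 1.0:
        raise QFormError("p-values must lie in (0, 1]")
    return float(np.sqrt(stats.chi2.isf(p, df=1)))


def combine_pvalues_product_normal(
    p1: float, p2: float, sign: int = 1, accuracy: float = DEFAULT_ACCURACY
) -> float:
    """Multiplicative (product-normal) combination of two p-values.

    Each p-value is mapped to a magnitude ``z = sqrt(inv-chi2_1(1 - p))``, the
    signed product ``sign * z1 * z2`` is formed, and the coherent (sign=+1,
    right tail) or anti-coherent (sign=-1, left tail) product-normal
    probability at rho=0 is returned.  Unlike Fisher's additive combination,
    evidence combines multiplicatively: a p-value near 1 drags any partner
    towards non-significance.
    """
    if sign not in (1, -1):
        raise QFormError("sign must be +1 or -1")
    stat = _p_to_z(p1) * _p_to_z(p2)
    mix = ChiSquareMixture([0.5, -0.5], [1, 1])
    if sign == 1:
        return mixture_tail(mix, stat, "right", accuracy).probability
    return mixture_tail(mix, -stat, "left", accuracy).probability


def fisher_combine(p1: float, p2: float) -> float:
    """Fisher's additive combination: chi2_4 right tail of -2(log p1 + log p2)."""
    for p in (p1, p2):
        if not 0.0 < p <= 1.0:
            raise QFormError("p-values must lie in (0, 1]")
    return float(stats.chi2.sf(-2.0 * (np.log(p1) + np.log(p2)), df=4))
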