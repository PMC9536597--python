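"""Shared fixtures and independent Monte-Carlo oracle helpers.

The oracle helpers below deliberately use only numpy/scipy primitives (never
package code) so that tests compare two independent computational routes.
"""

from __future__ import annotations

import numpy as np
import pytest


def mc_mixture_right_tail(coeffs, dofs, x, n_draws, rng, chunk=1_000_000):
    """P(sum_i a_i chi2_{n_i} > x) by direct simulation (chunked)."""
    hits = 0
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        acc = np.zeros(m)
        for a, n in zip(coeffs, dofs):
            acc += a * rng.chisquare(n, m)
        hits += int((acc > x).sum())
        done += m
    return hits / n_draws


def mc_bilinear_right_tail(sigma, x, n_draws, rng, chunk=500_000):
    """P(W'Z > x) for independent draws W, Z ~ N(0, sigma), by simulation."""
    C = np.linalg.cholesky(sigma + 1e-12 * np.eye(sigma.shape[0]))
    d = sigma.shape[0]
    hits = 0
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        W = rng.standard_normal((m, d)) @ C.T
        Z = rng.standard_normal((m, d)) @ C.T
        hits += int(((W * Z).sum(axis=1) > x).sum())
        done += m
    return hits / n_draws


def mc_quadratic_right_tail(sigma, x, n_draws, rng, chunk=500_000):
    """P(Z'Z > x) for Z ~ N(0, sigma), by simulation."""
    C = np.linalg.cholesky(sigma + 1e-12 * np.eye(sigma.shape[0]))
    d = sigma.shape[0]
    hits = 0
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        Z = rng.standard_normal((m, d)) @ C.T
        hits += int(((Z * Z).sum(axis=1) > x).sum())
        done += m
    return hits / n_draws


def binom_se(p, n):
    return np.sqrt(max(p * (1.0 - p), 1.0 / n) / n)


def oracle_se(p_exact, p_mc, n):
    """Binomial SE for an exact-vs-MC comparison.

    Uses the larger of the two variance estimates so that an MC estimate
    sitting exactly on 0 or 1 does not collapse the tolerance.
    """
    v = max(p_exact * (1.0 - p_exact), p_mc * (1.0 - p_mc), 1.0 / n)
    return np.sqrt(v / n)


def assert_mc_agreement(p_exact, draw_mc, n_draws, context=None):
    """Assert |p_exact - MC| < 3 SE, re-drawing once on a marginal excess.

    ``draw_mc()`` must produce a fresh, independent Monte-Carlo estimate.
    A single >3-SE draw out of many instances is expected noise; a systematic
    error reproduces in the independent second batch and still fails.
    """
    for attempt in range(2):
        mc = draw_mc()
        if abs(p_exact - mc) < 3.0 * oracle_se(p_exact, mc, n_draws):
            return
    raise AssertionError(
        f"exact {p_exact} vs MC {mc} beyond 3 SE twice ({context})"
    )


def random_correlation(dim, rng):
    """A full-rank random correlation matrix (sample correlation of a wide
    Gaussian data matrix)."""
    if dim == 1:
        return np.ones((1, 1))
    X = rng.standard_normal((4 * dim + 20, dim))
    R = np.corrcoef(X, rowvar=False)
    return (R + R.T) / 2.0


@pytest.fixture(scope="session")
def sim_fixture_dir(tmp_path_factory):
    """A small complete simulated study shared across integration tests."""
    from crossgwas import SimConfig, simulate_gwas_fixture

    cfg = SimConfig(
        n_snps=60,
        n_samples=400,
        ld_structure=("blocks", [(10, 0.5)] * 6),
        seed=11,
        snps_per_gene=10,
    )
    out = tmp_path_factory.mktemp("sim")
    paths = simulate_gwas_fixture(cfg, out)
    return cfg, paths
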