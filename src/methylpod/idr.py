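"""Irreproducible discovery rate from a two-component rank-copula mixture.

Candidate scores from a replicate pair are rank-transformed to pseudo-uniform
values and mapped through the standard normal quantile. The resulting pairs
are modelled as a mixture of a fixed "irreproducible" component (standard
bivariate normal, correlation 0) and a "reproducible" component
N((mu, mu), sigma^2, rho) fitted by EM. The posterior probability of the
irreproducible component is the local idr; sorting candidates by local idr
and cumulatively averaging gives the global IDR used for filtering.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import stats


class IdrConvergenceWarning(UserWarning):
    pass


def _pseudo_z(scores: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(scores, method="average")
    u = ranks / (len(scores) + 1)
    return stats.norm.ppf(u)


def _bvn_logpdf(z1, z2, mu, sigma2, rho):
    det = sigma2 * sigma2 * (1 - rho**2)
    d1, d2 = z1 - mu, z2 - mu
    quad = (d1**2 - 2 * rho * d1 * d2 + d2**2) / (sigma2 * (1 - rho**2))
    return -0.5 * (np.log(4 * np.pi**2 * det) + quad)


def _mixture_quantile(u: np.ndarray, pi: float, mu: float, sigma: float) -> np.ndarray:
    """Inverse CDF of the mixture marginal (1-pi) N(0,1) + pi N(mu, sigma^2),
    by monotone interpolation on a dense grid."""
    lo = min(-6.0, mu - 6 * sigma)
    hi = max(6.0, mu + 6 * sigma)
    grid = np.linspace(lo, hi, 4096)
    cdf = (1 - pi) * stats.norm.cdf(grid) + pi * stats.norm.cdf(grid, mu, sigma)
    return np.interp(u, cdf, grid)


def fit_idr_pair(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    outer_iter: int = 40,
) -> tuple[np.ndarray, bool]:
    """Global IDR per candidate for one replicate pair.

    Scores are rank-transformed to pseudo-uniform values and mapped to
    pseudo-data through the inverse marginal CDF of the current mixture
    (the semiparametric step), alternating with EM updates of the
    reproducible component. Returns (global_idr, converged); higher scores
    mean stronger signal.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    n = len(a)
    if n != len(b):
        raise ValueError("score vectors differ in length")
    u1 = stats.rankdata(a, method="average") / (n + 1)
    u2 = stats.rankdata(b, method="average") / (n + 1)
    pi, mu, sigma2, rho = 0.5, 2.0, 1.0, 0.8
    gamma = np.full(n, 0.5)
    converged = False
    params_old = np.array([pi, mu, sigma2, rho])
    for _ in range(outer_iter):
        sigma = np.sqrt(sigma2)
        z1 = _mixture_quantile(u1, pi, mu, sigma)
        z2 = _mixture_quantile(u2, pi, mu, sigma)
        log_null = _bvn_logpdf(z1, z2, 0.0, 1.0, 0.0)
        ll_old = -np.inf
        for _ in range(max_iter):
            log_rep = _bvn_logpdf(z1, z2, mu, sigma2, rho)
            lw1 = np.log(pi) + log_rep
            lw0 = np.log1p(-pi) + log_null
            m = np.maximum(lw1, lw0)
            denom = m + np.log(np.exp(lw1 - m) + np.exp(lw0 - m))
            gamma = np.exp(lw1 - denom)  # P(reproducible | data)
            ll = float(denom.sum())
            if abs(ll - ll_old) < tol:
                break
            ll_old = ll
            w = gamma.sum()
            if w < 1e-6 or w > n - 1e-6:
                break  # degenerate mixture
            pi = min(max(w / n, 1e-4), 1 - 1e-4)
            mu = float((gamma * (z1 + z2)).sum() / (2 * w))
            d1, d2 = z1 - mu, z2 - mu
            sigma2 = max(float((gamma * (d1**2 + d2**2)).sum() / (2 * w)), 1e-6)
            rho = float((gamma * d1 * d2).sum() / (w * sigma2))
            rho = min(max(rho, -0.998), 0.998)
        params = np.array([pi, mu, sigma2, rho])
        if np.max(np.abs(params - params_old)) < 1e-4:
            converged = True
            break
        params_old = params
    local_idr = 1.0 - gamma
    order = np.argsort(local_idr)
    cum = np.cumsum(local_idr[order]) / np.arange(1, n + 1)
    global_idr = np.empty(n)
    global_idr[order] = cum
    return global_idr, converged


def pairwise_max_idr(score_matrix: np.ndarray) -> tuple[np.ndarray, bool]:
    """Worst (largest) pairwise global IDR per candidate over all replicate
    pairs; conservative multi-replicate rule."""
    k, n = score_matrix.shape
    if k < 2:
        raise ValueError("IDR requires >= 2 replicates")
    worst = np.zeros(n)
    all_ok = True
    for i in range(k):
        for j in range(i + 1, k):
            gi, ok = fit_idr_pair(score_matrix[i], score_matrix[j])
            all_ok = all_ok and ok
            worst = np.maximum(worst, gi)
    if not all_ok:
        warnings.warn(
            "IDR EM did not converge for at least one replicate pair",
            IdrConvergenceWarning,
        )
    return worst, all_ok
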