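"""Shared statistical primitives.

Poisson tail probabilities, Benjamini-Hochberg adjustment, Fisher's exact
odds ratios, and a small batched IRLS engine for fitting many GLMs that
share one design matrix (one fit per MPRA tile, per gRNA, or per gene).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "poisson_upper_tail",
    "bh_adjust",
    "fisher_odds_ratio",
    "estimate_nb_dispersion",
    "pearson_nb_dispersion",
    "batched_glm",
]

_ETA_CLIP = 30.0


def poisson_upper_tail(observed, expected):
    """One-sided P(X >= observed) for X ~ Poisson(expected).

    Vectorized; observed == 0 gives exactly 1.0.
    """
    observed = np.asarray(observed)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expected must be non-negative")
    # sf(k-1) = P(X >= k); exact at k = 0 because sf(-1) = 1
    return sps.poisson.sf(observed - 1, expected)


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fisher_odds_ratio(table):
    """Odds ratio and two-sided Fisher exact p for a 2x2 count table.

    The odds ratio uses the Haldane-Anscombe 0.5 continuity correction
    whenever any cell is zero; the p-value is the exact hypergeometric
    two-sided probability.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oddsratio = (a * d) / (b * c)
    p = sps.fisher_exact(np.round(t).astype(int), alternative="two-sided")[1]
    return float(oddsratio), float(p)


def pearson_nb_dispersion(Y, mu, ddof, floor=1e-4, max_alpha=100.0):
    """NB dispersion matching the Pearson chi-square to its residual df.

    Solves sum_i (y_i - mu_i)^2 / (mu_i (1 + alpha mu_i)) = ddof per row
    by bisection.  The df correction matters when each fit has only a
    handful of observations: the naive moment estimator ignores the
    variance absorbed by the fitted means and is badly biased low there.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    mu = np.maximum(np.atleast_2d(np.asarray(mu, dtype=float)), 1e-8)
    if ddof < 1:
        raise ValueError("ddof must be at least 1")
    G = Y.shape[0]
    res2 = (Y - mu) ** 2

    def pearson(a):
        return (res2 / (mu * (1.0 + a[:, None] * mu))).sum(axis=1)

    underdispersed = pearson(np.zeros(G)) <= ddof
    lo = np.zeros(G)
    hi = np.full(G, max_alpha)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_big = pearson(mid) > ddof
        lo = np.where(too_big, mid, lo)
        hi = np.where(too_big, hi, mid)
    alpha = np.where(underdispersed, 0.0, 0.5 * (lo + hi))
    return np.maximum(alpha, floor)


def estimate_nb_dispersion(y, mu, floor=1e-4):
    """Method-of-moments NB dispersion alpha with Var = mu + alpha*mu^2.

    Accepts 1-D (single fit) or 2-D (groups x observations) arrays; the
    estimate is floored so downstream weights stay finite.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    num = ((y - mu) ** 2 - mu).sum(axis=-1)
    den = (mu**2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.maximum(alpha, floor)


def _irls_chunk(X, Y, family, alpha, offset, max_iter, tol, ridge):
    G, n = Y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    # start the intercept near the data scale for log-link families
    if family in ("poisson", "nb"):
        if offset is not None:
            scale = np.maximum(
                np.exp(np.clip(offset, -_ETA_CLIP, _ETA_CLIP)).mean(axis=-1), 1e-12
            )
        else:
            scale = 1.0
        beta[:, 0] = np.log(np.maximum(Y.mean(axis=1) / scale, 1e-3))
    eye = ridge * np.eye(p)
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        eta = beta @ X.T
        if offset is not None:
            eta = eta + offset
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        if family in ("poisson", "nb"):
            mu = np.exp(eta)
            dmu = mu
            W = mu if family == "poisson" else mu / (1.0 + alpha[:, None] * mu)
        else:  # binomial, logit link
            mu = 1.0 / (1.0 + np.exp(-eta))
            dmu = mu * (1.0 - mu)
            W = np.clip(dmu, 1e-10, None)
        z = (eta - (offset if offset is not None else 0.0)) + (Y - mu) / np.clip(
            dmu, 1e-12, None
        )
        XWt = (X[None, :, :] * W[:, :, None]).transpose(0, 2, 1)  # (G, p, n)
        A = XWt @ X + eye
        b = (XWt @ z[:, :, None])[:, :, 0]
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        step = np.abs(new_beta - beta).max(axis=1)
        beta = new_beta
        converged = step < tol
        if converged.all():
            break
    # final quantities
    eta = beta @ X.T
    if offset is not None:
        eta = eta + offset
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    if family in ("poisson", "nb"):
        mu = np.exp(eta)
        W = mu if family == "poisson" else mu / (1.0 + alpha[:, None] * mu)
    else:
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = np.clip(mu * (1.0 - mu), 1e-10, None)
    XWt = (X[None, :, :] * W[:, :, None]).transpose(0, 2, 1)
    A = XWt @ X + eye
    cov = np.linalg.inv(A)
    return beta, cov, mu, converged


def batched_glm(
    X,
    Y,
    family="poisson",
    alpha=None,
    offset=None,
    max_iter=60,
    tol=1e-9,
    ridge=1e-8,
    chunk_elems=20_000_000,
):
    """Fit G GLMs sharing one design matrix via IRLS.

    Parameters
    ----------
    X : (n, p) design matrix, first column assumed to be the intercept.
    Y : (G, n) response matrix, one row per fit.
    family : 'poisson', 'nb' (log link) or 'binomial' (logit link).
    alpha : NB dispersion, scalar or length-G (Var = mu + alpha*mu^2).
    offset : optional (n,) or (G, n) linear-predictor offset.

    Returns dict with beta (G, p), cov (G, p, p), mu (G, n), converged (G,).
    Groups are processed in chunks to bound the (chunk, n, p) workspace.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, n = Y.shape
    p = X.shape[1]
    if X.shape[0] != n:
        raise ValueError("X rows must match Y columns")
    if family == "nb":
        alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (G,)).copy()
        if np.any(alpha <= 0):
            raise ValueError("NB dispersion must be positive")
    off2d = None
    if offset is not None:
        offset = np.asarray(offset, dtype=float)
        off2d = np.broadcast_to(offset, (G, n)) if offset.ndim == 1 else offset
    chunk = max(1, int(chunk_elems // max(n * p, 1)))
    betas, covs, mus, convs = [], [], [], []
    for lo in range(0, G, chunk):
        hi = min(G, lo + chunk)
        a = alpha[lo:hi] if family == "nb" else None
        o = off2d[lo:hi] if off2d is not None else None
        b, c, m, cv = _irls_chunk(X, Y[lo:hi], family, a, o, max_iter, tol, ridge)
        betas.append(b)
        covs.append(c)
        mus.append(m)
        convs.append(cv)
    return {
        "beta": np.concatenate(betas),
        "cov": np.concatenate(covs),
        "mu": np.concatenate(mus),
        "converged": np.concatenate(convs),
    }
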