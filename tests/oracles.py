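"""Independent reference implementations used only to cross-check results.

These deliberately use naive routes (dense matrices, per-group loops,
textbook formulas) so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np


def hudson_fst(d1: np.ndarray, d2: np.ndarray) -> float:
    """Hudson-style two-population Fst, ratio of averages over loci.

    ``d1, d2`` are dosage matrices (individuals x loci, -1 = missing).
    Numerator (p1-p2)^2 with within-sample corrections, denominator the
    between-population heterozygosity.
    """
    def freqs(d):
        obs = d >= 0
        n = 2 * obs.sum(axis=0).astype(float)
        p = np.where(obs, d, 0).sum(axis=0) / np.maximum(n, 1)
        return p, n

    p1, n1 = freqs(d1)
    p2, n2 = freqs(d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = np.isfinite(num) & np.isfinite(den) & (den > 0)
    return float(num[ok].sum() / den[ok].sum())


def dense_reml_loglik(y, X, groups, loglam) -> float:
    """REML log-likelihood via explicit dense covariance matrices."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    n, p = X.shape
    Z = (groups[:, None] == np.unique(groups)[None, :]).astype(float)
    lam = np.exp(loglam)
    V = np.eye(n) + lam * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    rss = r @ Vi @ r
    s2 = rss / (n - p)
    _, ldv = np.linalg.slogdet(V)
    _, ldx = np.linalg.slogdet(XtVX)
    return float(-0.5 * ((n - p) * (np.log(2 * np.pi * s2) + 1) + ldv + ldx))


def wc_fst_single_locus(sizes, freqs, hets):
    """Weir & Cockerham (1984) theta for one biallelic locus, by the book.

    ``sizes``: diploid sample sizes per population; ``freqs``: alt allele
    frequencies; ``hets``: observed heterozygote proportions.  Returns
    (a, b, c, Fst) with plain Python loops.
    """
    sizes = [float(s) for s in sizes]
    r = len(sizes)
    nbar = sum(sizes) / r
    nc = (r * nbar - sum(s * s for s in sizes) / (r * nbar)) / (r - 1)
    pbar = sum(s * p for s, p in zip(sizes, freqs)) / (r * nbar)
    s2 = sum(s * (p - pbar) ** 2 for s, p in zip(sizes, freqs)) / ((r - 1) * nbar)
    hbar = sum(s * h for s, h in zip(sizes, hets)) / (r * nbar)
    a = nbar / nc * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c, a / (a + b + c)


def wc_fst_from_panel(dosages, labels):
    """Mean corrected WC Fst over loci, ratio of sums, via the scalar oracle."""
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels))
    num = den = 0.0
    for j in range(dosages.shape[1]):
        sizes, freqs, hets = [], [], []
        for g in groups:
            d = dosages[labels == g, j]
            d = d[d >= 0]
            if len(d) == 0:
                continue
            sizes.append(len(d))
            freqs.append(d.sum() / (2 * len(d)))
            hets.append((d == 1).mean())
        if len(sizes) < 2 or min(sizes) < 2:
            continue
        a, b, c, _ = wc_fst_single_locus(sizes, freqs, hets)
        num += a
        den += a + b + c
    return num / den


def als_ridge(Y, Xc, k, lam, n_iter=200):
    """Plain alternating minimization for the rank-k ridge decomposition."""
    B = np.linalg.solve(Xc.T @ Xc + lam * np.eye(Xc.shape[1]), Xc.T @ Y).T
    U = np.zeros((Y.shape[0], k))
    V = np.zeros((Y.shape[1], k))
    for _ in range(n_iter):
        R = Y - Xc @ B.T
        uu, ss, vv = np.linalg.svd(R, full_matrices=False)
        U = uu[:, :k] * ss[:k]
        V = vv[:k].T
        B = np.linalg.solve(
            Xc.T @ Xc + lam * np.eye(Xc.shape[1]), Xc.T @ (Y - U @ V.T)).T
    resid = Y - U @ V.T - Xc @ B.T
    return float(np.sum(resid**2) + lam * np.sum(B**2))


def ols_via_qr(X, y):
    """Least squares through an explicit QR decomposition."""
    Q, R = np.linalg.qr(X)
    return np.linalg.solve(R, Q.T @ y)
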