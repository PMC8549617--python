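"""Latent factor mixed model association with ridge estimation.

Here the genotype matrix is the response: Y (individuals x SNPs,
standardized) is decomposed as Y = U V' + X B' + E, where X holds the
observed covariates (sqrt muscle mercury, sediment mercury, sex,
length), U V' is a rank-K latent term absorbing population structure
and other unobserved confounders, and B carries per-SNP covariate
effects under a ridge penalty:

    min ||Y - U V' - X B'||_F^2 + lambda ||B||_F^2

The global minimizer is analytic: with the SVD X = Q Sigma R', the
objective equals ||Phi (Y - W)||^2 in W = U V' for an invertible map
Phi that shrinks the covariate subspace, so W is Phi^-1 applied to the
rank-K truncated SVD of Phi Y, and B solves the ridge system on the
residual.  Association tests then regress each SNP on [X, U] by OLS and
calibrate the target covariate's statistics with a genomic inflation
factor (median z^2 over the chi-square(1) median).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CHI2_1_MEDIAN = 0.45493642311957283  # scipy.stats.chi2.ppf(0.5, 1)


class LfmmError(ValueError):
    pass


@dataclass
class LatentFactorModel:
    U: np.ndarray            # N x K latent scores
    V: np.ndarray            # M x K loadings
    B: np.ndarray            # M x d covariate effects
    ridge_penalty: float
    n_factors: int
    covariate_names: list
    x_means: np.ndarray      # column means removed from X before fitting


@dataclass
class CalibratedTests:
    table: pd.DataFrame      # z, p_raw, p_calibrated per SNP
    gif: float
    target: str


def _as_matrix(Y) -> np.ndarray:
    if hasattr(Y, "X"):  # StandardizedGenotypes
        return np.asarray(Y.X, dtype=float)
    return np.asarray(Y, dtype=float)


def _covariates(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def ridge_objective(Y, X_centered, U, V, B, lam: float) -> float:
    """The penalized Frobenius objective at (U, V, B)."""
    resid = Y - U @ V.T - X_centered @ B.T
    return float(np.sum(resid**2) + lam * np.sum(B**2))


def fit_latent_factor_ridge(
    Y,
    X,
    n_factors: int = 7,
    ridge_penalty: float = 1e-5,
) -> LatentFactorModel:
    """Global minimizer of the rank-K ridge decomposition of Y.

    ``n_factors=7`` by default: the leading principal components that
    absorb metapopulation structure.  ``ridge_penalty`` defaults to a
    near-zero value (the penalty mainly stabilizes the covariate block).
    Covariates are column-centered internally; they must be full rank.
    """
    Y = _as_matrix(Y)
    Xm, names = _covariates(X)
    n, m = Y.shape
    if Xm.shape[0] != n:
        raise LfmmError("Y and X disagree on the number of individuals")
    k = int(n_factors)
    if k > min(n, m):
        raise LfmmError(f"n_factors={k} exceeds min(N, M)={min(n, m)}")
    if k < 0 or ridge_penalty < 0:
        raise LfmmError("n_factors and ridge_penalty must be non-negative")
    x_means = Xm.mean(axis=0)
    Xc = Xm - x_means
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        raise LfmmError(
            "collinear covariates (rank "
            f"{rank} < {Xc.shape[1]}): {names}")

    d = Xc.shape[1]
    if k == 0:
        U = np.zeros((n, 0))
        V = np.zeros((m, 0))
        B = _ridge_b(Y, Xc, ridge_penalty)
    elif ridge_penalty > 0:
        Q, sig, _ = np.linalg.svd(Xc, full_matrices=False)
        shrink = np.sqrt(ridge_penalty / (sig**2 + ridge_penalty))
        # Phi = I + Q (shrink - 1) Q' ; Phi^-1 = I + Q (1/shrink - 1) Q'
        PhiY = Y + Q @ ((shrink - 1)[:, None] * (Q.T @ Y))
        uu, ss, vv = np.linalg.svd(PhiY, full_matrices=False)
        Uk = uu[:, :k] * ss[:k]
        U = Uk + Q @ ((1 / shrink - 1)[:, None] * (Q.T @ Uk))
        V = vv[:k].T
        B = _ridge_b(Y - U @ V.T, Xc, ridge_penalty)
    else:
        U, V, B = _als(Y, Xc, k, 0.0)
    return LatentFactorModel(
        U=U, V=V, B=B, ridge_penalty=float(ridge_penalty),
        n_factors=k, covariate_names=names, x_means=x_means)


def _ridge_b(resid: np.ndarray, Xc: np.ndarray, lam: float) -> np.ndarray:
    d = Xc.shape[1]
    if lam > 0:
        return np.linalg.solve(Xc.T @ Xc + lam * np.eye(d), Xc.T @ resid).T
    return np.linalg.lstsq(Xc, resid, rcond=None)[0].T


def _als(Y, Xc, k, lam, n_iter: int = 200, tol: float = 1e-10):
    """Alternating least squares on (W, B); oracle/fallback route."""
    B = _ridge_b(Y, Xc, lam)
    prev = np.inf
    U = np.zeros((Y.shape[0], k))
    V = np.zeros((Y.shape[1], k))
    for _ in range(n_iter):
        R = Y - Xc @ B.T
        uu, ss, vv = np.linalg.svd(R, full_matrices=False)
        U = uu[:, :k] * ss[:k]
        V = vv[:k].T
        B = _ridge_b(Y - U @ V.T, Xc, lam)
        obj = ridge_objective(Y, Xc, U, V, B, lam)
        if prev - obj < tol * max(1.0, abs(prev)):
            break
        prev = obj
    return U, V, B


def genomic_inflation_factor(z) -> float:
    """Median(z^2) over the chi-square(1) median (0.4549...)."""
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < 10:
        raise LfmmError("need at least 10 finite statistics for the GIF")
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def lfmm_association_test(
    model: LatentFactorModel,
    Y,
    X,
    target: str | int = 0,
    snp_ids=None,
) -> CalibratedTests:
    """Per-SNP test of one covariate, GIF-calibrated.

    Each SNP column of Y is regressed by OLS on an intercept, the
    centered covariates and the fitted latent scores U; the t-statistic
    of the target covariate is the z-score.  The genomic inflation
    factor rescales z^2 before the chi-square(1) upper-tail p-value.
    """
    Y = _as_matrix(Y)
    Xm, names = _covariates(X)
    if isinstance(target, str):
        if target not in names:
            raise LfmmError(f"unknown covariate {target!r}; have {names}")
        t_idx = names.index(target)
        t_name = target
    else:
        t_idx = int(target)
        t_name = names[t_idx]
    Xc = Xm - model.x_means
    D = np.column_stack([np.ones(len(Y)), Xc, model.U])
    col = 1 + t_idx
    DtD = D.T @ D
    DtD_inv = np.linalg.inv(DtD)
    beta = DtD_inv @ (D.T @ Y)
    resid = Y - D @ beta
    dof = len(Y) - D.shape[1]
    if dof <= 0:
        raise LfmmError("more regressors than individuals in the test model")
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(sigma2 * DtD_inv[col, col])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta[col] / se, np.nan)
    gif = genomic_inflation_factor(z)
    z2 = z**2
    p_raw = stats.chi2.sf(z2, 1)
    p_cal = np.clip(stats.chi2.sf(z2 / gif, 1), 5e-324, 1.0)
    table = pd.DataFrame({
        "effect": beta[col],
        "z": z,
        "p_raw": p_raw,
        "p_calibrated": p_cal,
        "neglog10p_calibrated": -np.log10(p_cal),
    })
    if snp_ids is not None:
        table.insert(0, "snp_id", np.asarray(snp_ids))
    return CalibratedTests(table=table, gif=gif, target=t_name)
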