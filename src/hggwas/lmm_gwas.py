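"""Random-intercept linear mixed model GWAS and significance thresholds.

The per-SNP model is

    sqrt(Hg_muscle) ~ intercept + SNP dosage + sex + location:length
                      + (1 | location)

with the sampling location as the sole random effect, absorbing both
shared environment and within-location relatedness.  Estimation is REML
with the variance ratio lambda = sigma_b^2 / sigma_e^2 profiled out: for
fixed lambda the marginal covariance is block diagonal with one
rank-one block per location, so GLS quantities come from per-group sums
(the Sherman-Morrison identity) and lambda is maximized by bounded
one-dimensional search on log lambda.

Genome-wide significance uses the max-of-uniforms null: the largest
-log10 p among m independent null tests, simulated (the minimum of m
uniforms is Beta(1, m), so one Beta draw per replicate suffices) and
available in closed form as -log10(1 - q^(1/m)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import MISSING, GenotypePanel

LOG_LAMBDA_BOUNDS = (-10.0, 10.0)


class LmmError(ValueError):
    pass


@dataclass
class LmmFit:
    params: pd.Series          # fixed-effect estimates
    bse: pd.Series             # Wald standard errors
    pvalues: pd.Series         # two-sided Wald z-tests
    sigma2_b: float            # random-intercept variance
    sigma2_e: float            # residual variance
    lambda_v: float            # sigma2_b / sigma2_e
    loglik: float              # REML log-likelihood at the optimum
    n_obs: int
    n_groups: int
    converged: bool
    dropped_columns: list

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse


@dataclass
class NullThresholds:
    """Simulated family-wise -log10 p thresholds for m tests."""

    m: int
    reps: int
    seed: int
    median: float
    q95: float
    closed_form_median: float
    closed_form_q95: float
    method: str

    def __post_init__(self) -> None:
        if not self.q95 > self.median:
            raise LmmError("q95 must exceed the median")


# ---------------------------------------------------------------------------
# Scalar REML engine


def _drop_collinear(X: np.ndarray, names: list[str]):
    """Remove linearly dependent columns via pivoted QR."""
    if X.shape[1] == 0:
        return X, names, []
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0)
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    dropped = [names[i] for i in piv[rank:]]
    return X[:, keep], [names[i] for i in keep], dropped


def _group_index(groups) -> tuple[np.ndarray, np.ndarray]:
    codes, _ = pd.factorize(np.asarray(groups))
    sizes = np.bincount(codes)
    return codes, sizes


def _reml_pieces(loglam, XtX, Xty, yty, Sx, Sy, sizes, n, p):
    """GLS quantities at a given log variance ratio.

    Uses V*^-1 = I - sum_j lambda/(1 + n_j lambda) 1_j 1_j' so everything
    reduces to per-group sums Sx (groups x p) and Sy.
    """
    lam = np.exp(loglam)
    u = lam / (1 + sizes * lam)                   # per-group shrink factor
    XtVX = XtX - (Sx * u[:, None]).T @ Sx
    XtVy = Xty - Sx.T @ (u * Sy)
    yVy = yty - np.sum(u * Sy**2)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = yVy - beta @ XtVy
    logdet_v = np.sum(np.log1p(sizes * lam))
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise LmmError("X'V^-1 X not positive definite")
    return beta, rss, logdet_v, logdet_x, XtVX


def _reml_loglik_from_pieces(rss, logdet_v, logdet_x, n, p):
    nm = n - p
    sigma2 = rss / nm
    return -0.5 * (nm * (np.log(2 * np.pi * sigma2) + 1) + logdet_v + logdet_x)


def fit_random_intercept_lmm(
    y,
    fixed_design,
    groups,
    names: list[str] | None = None,
    tol: float = 1e-8,
) -> LmmFit:
    """REML fit of y = X beta + (1|group) + e by profiling the variance ratio.

    The profile REML criterion in log lambda is maximized by bounded
    Brent search on ``LOG_LAMBDA_BOUNDS``; a maximum at the lower bound is
    reported as the boundary fit sigma2_b = 0 (the OLS solution).
    """
    if isinstance(fixed_design, pd.DataFrame):
        names = list(fixed_design.columns)
        X = fixed_design.to_numpy(dtype=float)
    else:
        X = np.asarray(fixed_design, dtype=float)
        names = names or [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise LmmError("response contains non-finite values")
    if not np.isfinite(X).all():
        raise LmmError("design contains non-finite values")
    n = len(y)
    X, names, dropped = _drop_collinear(X, names)
    p = X.shape[1]
    if p == 0 or n <= p:
        raise LmmError("design has no usable columns or too few rows")
    codes, sizes = _group_index(groups)

    XtX, Xty, yty = X.T @ X, X.T @ y, y @ y
    ngroups = len(sizes)
    Sx = np.zeros((ngroups, p))
    np.add.at(Sx, codes, X)
    Sy = np.bincount(codes, weights=y, minlength=ngroups)

    def neg_loglik(loglam):
        _, rss, ldv, ldx, _ = _reml_pieces(
            loglam, XtX, Xty, yty, Sx, Sy, sizes, n, p)
        return -_reml_loglik_from_pieces(rss, ldv, ldx, n, p)

    lo, hi = LOG_LAMBDA_BOUNDS
    res = optimize.minimize_scalar(
        neg_loglik, bounds=(lo, hi), method="bounded",
        options={"xatol": tol})
    loglam = float(res.x)
    # explicit boundary handling: accept an endpoint if it beats the
    # interior optimum (the profile can be monotone)
    for edge in (lo, hi):
        if neg_loglik(edge) < res.fun:
            loglam = edge
    at_lower = loglam <= lo + 1e-6 or neg_loglik(lo) <= neg_loglik(loglam) + 1e-12
    if ngroups < 2:
        at_lower = True
    if at_lower:
        loglam = -np.inf  # sigma2_b = 0 -> plain OLS

    if np.isinf(loglam):
        beta, rss0, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        ldv = 0.0
        XtVX = XtX
        sign, ldx = np.linalg.slogdet(XtVX)
        lam = 0.0
    else:
        beta, rss, ldv, ldx, XtVX = _reml_pieces(
            loglam, XtX, Xty, yty, Sx, Sy, sizes, n, p)
        lam = float(np.exp(loglam))
    sigma2_e = rss / (n - p)
    sigma2_b = lam * sigma2_e
    loglik = _reml_loglik_from_pieces(rss, ldv, ldx, n, p)
    cov = sigma2_e * np.linalg.inv(XtVX)
    bse = np.sqrt(np.diag(cov))
    z = beta / bse
    pvals = 2 * stats.norm.sf(np.abs(z))
    return LmmFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2_b=float(sigma2_b),
        sigma2_e=float(sigma2_e),
        lambda_v=float(lam),
        loglik=float(loglik),
        n_obs=n,
        n_groups=ngroups,
        converged=bool(res.success),
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# Vectorized per-SNP scan

_GOLDEN = (np.sqrt(5) - 1) / 2


def _scan_design(panel: GenotypePanel, pheno: pd.DataFrame, sex) -> tuple:
    """Covariate design shared by all SNPs: intercept, sex, location:length."""
    merged = pheno.set_index("sample_id").reindex(panel.samples["id"])
    missing = merged["hg_muscle_ng_g_dw"].isna()
    if missing.any():
        raise LmmError(
            "phenotype table lacks sample(s): "
            + ", ".join(merged.index[missing][:5]))
    y = np.sqrt(merged["hg_muscle_ng_g_dw"].to_numpy(dtype=float))
    sex = np.asarray(sex, dtype=object).astype(str)
    if not np.isin(sex, ("M", "F")).all():
        raise LmmError("genetic sex must be available for all individuals")
    codes, sizes = _group_index(merged["location"].to_numpy())
    length = merged["length_mm"].to_numpy(dtype=float)
    L = len(sizes)
    loc_length = np.zeros((len(y), L))
    loc_length[np.arange(len(y)), codes] = length
    C = np.column_stack([
        np.ones(len(y)),
        (sex == "M").astype(float),
        loc_length,
    ])
    names = ["intercept", "sexM"] + [f"length:loc{g}" for g in range(L)]
    return y, C, names, codes, sizes


def _imputed_dosages(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Float dosage matrix with per-SNP mean imputation; flags monomorphics."""
    dos = panel.dosages.astype(float)
    obs = panel.dosages != MISSING
    dos[~obs] = np.nan
    means = np.nanmean(np.where(obs, dos, np.nan), axis=0)
    with np.errstate(invalid="ignore"):
        sds = np.nanstd(np.where(obs, dos, np.nan), axis=0)
    mono = ~(sds > 0) | (obs.sum(axis=0) < 2)
    S = np.where(obs, panel.dosages, means[None, :]).astype(float)
    return S, mono


def _batched_criterion(lam, sizes, pre):
    """REML criterion and Wald pieces for per-SNP variance ratios ``lam``.

    ``lam`` is a vector with one entry per SNP; all linear algebra is
    batched: the covariate block of the normal equations is a stacked
    (M, p, p) tensor assembled from per-group rank-one corrections.
    """
    CtC, CtS, Cty, yty, ssq, Sty, Sc, Sg, Sy, n, p0 = pre
    u = lam[None, :] / (1 + sizes[:, None] * lam[None, :])   # groups x M
    A0 = CtC[None] - np.einsum("jm,ja,jb->mab", u, Sc, Sc, optimize=True)
    a = CtS - Sc.T @ (u * Sg)                                # p0 x M
    d = ssq - np.sum(u * Sg**2, axis=0)                      # M
    r0 = Cty[None, :] - (u * Sy[:, None]).T @ Sc             # M x p0
    rs = Sty - np.sum(u * Sg * Sy[:, None], axis=0)          # M
    yVy = yty - np.sum(u * Sy[:, None] ** 2, axis=0)         # M

    sol = np.linalg.solve(A0, np.stack([a.T, r0], axis=-1))  # M x p0 x 2
    Qi_a, Qi_r0 = sol[..., 0], sol[..., 1]
    a_Qi_a = np.sum(a.T * Qi_a, axis=1)
    a_Qi_r0 = np.sum(a.T * Qi_r0, axis=1)
    schur = np.maximum(d - a_Qi_a, 1e-30)
    beta_s = (rs - a_Qi_r0) / schur
    rss = yVy - (np.sum(Qi_r0 * r0, axis=1) + beta_s * (rs - a_Qi_r0))
    rss = np.maximum(rss, 1e-300)
    _, ld0 = np.linalg.slogdet(A0)
    logdet_x = ld0 + np.log(schur)
    logdet_v = np.log1p(sizes[:, None] * lam[None, :]).sum(axis=0)
    nm = n - (p0 + 1)
    crit = nm * np.log(rss / nm) + logdet_v + logdet_x
    se = np.sqrt((rss / nm) / schur)
    return crit, beta_s, se, rss


def _shared_criterion(loglam, sizes, pre):
    """Criterion for all SNPs at one shared lambda (cheap coarse-grid pass)."""
    from scipy.linalg import cho_factor, cho_solve

    CtC, CtS, Cty, yty, ssq, Sty, Sc, Sg, Sy, n, p0 = pre
    lam = np.exp(loglam)
    u = lam / (1 + sizes * lam)                               # per group
    A0 = CtC - (Sc * u[:, None]).T @ Sc
    a = CtS - Sc.T @ (u[:, None] * Sg)                        # p0 x M
    d = ssq - u @ Sg**2
    r0 = Cty - Sc.T @ (u * Sy)
    rs = Sty - (u * Sy) @ Sg
    yVy = yty - np.sum(u * Sy**2)
    cho = cho_factor(A0)
    Qi_a = cho_solve(cho, a)
    Qi_r0 = cho_solve(cho, r0)
    a_Qi_r0 = a.T @ Qi_r0
    schur = np.maximum(d - np.sum(a * Qi_a, axis=0), 1e-30)
    beta_s = (rs - a_Qi_r0) / schur
    rss = np.maximum(yVy - (r0 @ Qi_r0 + beta_s * (rs - a_Qi_r0)), 1e-300)
    ld0 = 2 * np.sum(np.log(np.diag(cho[0])))
    logdet_x = ld0 + np.log(schur)
    logdet_v = np.sum(np.log1p(sizes * lam))
    nm = n - (p0 + 1)
    return nm * np.log(rss / nm) + logdet_v + logdet_x


def gwas_scan(
    panel: GenotypePanel,
    pheno: pd.DataFrame,
    sex,
    grid_points: int = 81,
    refine_iters: int = 30,
) -> pd.DataFrame:
    """Per-SNP random-intercept LMM scan of sqrt(muscle mercury).

    Fixed effects: intercept, additive SNP dosage (missing calls
    mean-imputed per SNP so n is constant across SNPs), sex, and a
    per-location length slope; random intercept on location.  Each SNP
    gets its own REML variance ratio: a shared coarse grid over
    log lambda brackets the per-SNP optimum, then vectorized golden-
    section search refines all SNPs at once.  Wald p-values for the SNP
    term; monomorphic SNPs are flagged with p = 1.
    """
    y, C, names, codes, sizes = _scan_design(panel, pheno, sex)
    S, mono = _imputed_dosages(panel)
    n, p0 = C.shape
    m = S.shape[1]

    ngroups = len(sizes)
    Z = np.zeros((len(y), ngroups))
    Z[np.arange(len(y)), codes] = 1.0
    Sc = Z.T @ C
    Sy = Z.T @ y
    Sg = Z.T @ S
    pre = (C.T @ C, C.T @ S, C.T @ y, y @ y, np.sum(S * S, axis=0),
           S.T @ y, Sc, Sg, Sy, n, p0)
    sizes = sizes.astype(float)

    # coarse pass: shared lambda grid, criterion for every SNP
    lo, hi = LOG_LAMBDA_BOUNDS
    grid = np.linspace(lo, hi, grid_points)
    crits = np.empty((grid_points, m))
    for k, loglam in enumerate(grid):
        crits[k] = _shared_criterion(loglam, sizes, pre)
    best = crits.argmin(axis=0)
    a_ = grid[np.maximum(best - 1, 0)]
    b_ = grid[np.minimum(best + 1, grid_points - 1)]

    # vectorized golden-section refinement, one bracket per SNP
    x1 = b_ - _GOLDEN * (b_ - a_)
    x2 = a_ + _GOLDEN * (b_ - a_)
    f1, *_ = _batched_criterion(np.exp(x1), sizes, pre)
    f2, *_ = _batched_criterion(np.exp(x2), sizes, pre)
    for _ in range(refine_iters):
        take1 = f1 < f2
        b_ = np.where(take1, x2, b_)
        a_ = np.where(take1, a_, x1)
        x1_cand = b_ - _GOLDEN * (b_ - a_)
        x2_cand = a_ + _GOLDEN * (b_ - a_)
        xe = np.where(take1, x1_cand, x2_cand)
        fe, *_ = _batched_criterion(np.exp(xe), sizes, pre)
        x1, x2, f1, f2 = (
            np.where(take1, x1_cand, x2),
            np.where(take1, x1, x2_cand),
            np.where(take1, fe, f2),
            np.where(take1, f1, fe),
        )
    loglam_hat = (a_ + b_) / 2
    # a minimum pinned at the lower grid edge is the boundary sigma2_b -> 0
    lam_hat = np.exp(loglam_hat)
    crit, beta, se, _ = _batched_criterion(lam_hat, sizes, pre)

    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 5e-324, 1.0)
    flags = np.where(mono, "monomorphic", "")
    beta = np.where(mono, np.nan, beta)
    se = np.where(mono, np.nan, se)
    z = np.where(mono, 0.0, z)
    p = np.where(mono, 1.0, p)

    out = pd.DataFrame({
        "snp_id": panel.snps["id"].to_numpy(),
        "chrom": panel.snps["chrom"].to_numpy(),
        "pos": panel.snps["pos"].to_numpy(),
        "effect": beta,
        "se": se,
        "stat": z,
        "p": p,
        "neglog10p": -np.log10(p),
        "n": n,
        "lambda_v": lam_hat,
        "flag": flags,
        "converged": True,
    })
    chrom_order = {c: i for i, c in enumerate(pd.unique(out["chrom"]))}
    out = out.sort_values(
        ["chrom", "pos"],
        key=lambda s: s.map(chrom_order) if s.name == "chrom" else s,
    ).reset_index(drop=True)
    return out


def snp_design(panel: GenotypePanel, pheno: pd.DataFrame, sex, snp_id: str):
    """Response, full fixed design (with the SNP column) and groups for one SNP."""
    y, C, names, codes, _ = _scan_design(panel, pheno, sex)
    j = panel.snps.index[panel.snps["id"] == snp_id]
    if len(j) != 1:
        raise LmmError(f"SNP {snp_id!r} not present in the panel")
    S, mono = _imputed_dosages(panel.subset(snp_idx=[int(j[0])]))
    if mono[0]:
        raise LmmError(f"SNP {snp_id!r} is monomorphic in the analysis set")
    X = np.column_stack([C[:, :1], S[:, 0], C[:, 1:]])
    names = [names[0], "snp"] + names[1:]
    return y, X, names, codes


def standardized_effect_size(
    panel: GenotypePanel, pheno: pd.DataFrame, sex, snp_id: str,
) -> tuple[float, float]:
    """Per-allele effect of one SNP in phenotype-SD units.

    sqrt(mercury) is z-scored over the analysis set and the scan's mixed
    model refitted for this SNP alone; returns (|beta_snp|, SE).
    """
    y, X, names, codes = snp_design(panel, pheno, sex, snp_id)
    yz = (y - y.mean()) / y.std(ddof=1)
    fit = fit_random_intercept_lmm(yz, X, codes, names=names)
    return abs(float(fit.params["snp"])), float(fit.bse["snp"])


# ---------------------------------------------------------------------------
# Genome-wide significance thresholds


def max_logp_closed_form(q: float, m: int) -> float:
    """Quantile q of the max of m independent -log10 Uniform(0,1) draws."""
    return float(-np.log10(-np.expm1(np.log(q) / m)))


def simulate_max_logp_null(
    m: int,
    reps: int = 10_000,
    seed: int = 0,
    method: str = "beta",
) -> NullThresholds:
    """Simulate the family-wise null distribution of the top -log10 p.

    Per replicate the maximum of m independent -log10 Uniform(0,1) draws;
    ``method="beta"`` uses the order-statistic shortcut (the minimum of m
    uniforms is Beta(1, m)), ``method="direct"`` draws all m uniforms.
    """
    if m < 1 or reps < 100:
        raise LmmError("need m >= 1 and reps >= 100")
    rng = np.random.default_rng(seed)
    if method == "beta":
        min_p = rng.beta(1, m, size=reps)
        maxima = -np.log10(min_p)
    elif method == "direct":
        maxima = np.empty(reps)
        chunk = max(1, int(2e7) // m)
        for start in range(0, reps, chunk):
            stop = min(start + chunk, reps)
            u = rng.random((stop - start, m))
            maxima[start:stop] = -np.log10(u.min(axis=1))
    else:
        raise LmmError(f"unknown method {method!r}")
    return NullThresholds(
        m=m,
        reps=reps,
        seed=seed,
        median=float(np.median(maxima)),
        q95=float(np.quantile(maxima, 0.95)),
        closed_form_median=max_logp_closed_form(0.5, m),
        closed_form_q95=max_logp_closed_form(0.95, m),
        method=method,
    )


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Family-wise threshold alpha/m, returned as (p, -log10 p)."""
    if not 0 < alpha < 1 or m < 1:
        raise LmmError("need 0 < alpha < 1 and m >= 1")
    t = alpha / m
    return t, float(-np.log10(t))
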