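"""Fst outlier detection with a trimmed-likelihood chi-square null.

Per-locus differentiation is measured with Weir & Cockerham (1984)
variance components computed from per-group allele frequencies and
heterozygosities.  Two estimators are kept: the finite-sample corrected
Fst, and an uncorrected variant (the large-sample limit of the
correction factors) whose neutral distribution is well approximated by
a scaled chi-square — the basis of the outlier test.  The neutral null
(mean Fst and effective degrees of freedom) is inferred by maximum
likelihood on the central body of the empirical distribution: loci below
a heterozygosity threshold are removed and both Fst tails trimmed, with
the likelihood truncated to the kept interval.  Right-tail p-values from
the fitted null flag excessively differentiated loci; Benjamini-Hochberg
converts them to q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import MISSING, SEX_CHROMOSOME, GenotypePanel


class OutflankError(ValueError):
    pass


@dataclass
class ChiSqFit:
    df_inferred: float
    fst_bar: float
    trim_low: float
    trim_high: float
    he_min: float
    n_loci_used: int
    truncation: tuple[float, float]
    loglik: float
    at_bound: bool


@dataclass
class OutlierScan:
    grouping: str
    fst_table: pd.DataFrame
    fit: ChiSqFit
    n_outliers: int


def _group_counts(panel: GenotypePanel, labels) -> tuple[np.ndarray, ...]:
    """Per-group sample sizes, allele frequencies and het proportions.

    Missing genotypes are excluded locus-wise, so n varies per (group,
    locus).  Arrays are groups x loci.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    Z = np.stack([(labels == g).astype(float) for g in groups])  # G x N
    obs = (panel.dosages != MISSING).astype(float)               # N x M
    dos = np.where(panel.dosages == MISSING, 0, panel.dosages).astype(float)
    n = Z @ obs                                                  # G x M
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (Z @ dos) / (2 * n)
        h = (Z @ ((panel.dosages == 1) & (obs > 0)).astype(float)) / n
    return groups, n, p, h


def weir_cockerham_components(n, p, h):
    """WC84 variance components a, b, c per locus, plus uncorrected ones.

    ``n, p, h`` are groups x loci arrays of sample sizes, allele
    frequencies and observed heterozygosity; groups with no data at a
    locus drop out of that locus.  The uncorrected components replace
    the finite-sample correction factors by their large-n limits, which
    is what makes the neutral values chi-square distributed.
    """
    present = n > 0
    r = present.sum(axis=0).astype(float)
    n_ = np.where(present, n, 0.0)
    p_ = np.where(present, p, 0.0)
    h_ = np.where(present, h, 0.0)
    n_tot = n_.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_tot / r
        nc = (n_tot - (n_**2).sum(axis=0) / n_tot) / (r - 1)
        pbar = (n_ * p_).sum(axis=0) / n_tot
        s2 = (n_ * (p_ - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_ * h_).sum(axis=0) / n_tot
        pq = pbar * (1 - pbar)
        inner = pq - s2 * (r - 1) / r - hbar / 4
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pq - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        a_nc = nbar / nc * s2
        b_nc = pq - s2 * (r - 1) / r - hbar / 2
        c_nc = hbar / 2
    he = 2 * pbar * (1 - pbar)
    return a, b, c, a_nc, b_nc, c_nc, he, r, nbar


def per_locus_fst(panel: GenotypePanel, group_labels) -> pd.DataFrame:
    """Weir-Cockerham Fst per biallelic locus, corrected and uncorrected.

    Loci genotyped in fewer than two groups (with at least two
    individuals each) are flagged rather than dropped.
    """
    groups, n, p, h = _group_counts(panel, group_labels)
    if len(groups) < 2:
        raise OutflankError("need at least 2 groups for Fst")
    a, b, c, a_nc, b_nc, c_nc, he, r, nbar = weir_cockerham_components(n, p, h)
    denom = a + b + c
    denom_nc = a_nc + b_nc + c_nc
    usable = ((n >= 2).sum(axis=0) >= 2) & (denom != 0) & (denom_nc != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(usable, a / denom, np.nan)
        fst_nc = np.where(usable, a_nc / denom_nc, np.nan)
    return pd.DataFrame({
        "snp_id": panel.snps["id"].to_numpy(),
        "chrom": panel.snps["chrom"].to_numpy(),
        "pos": panel.snps["pos"].to_numpy(),
        "He": he,
        "Fst": fst,
        "FstNoCorr": fst_nc,
        "T1": a,
        "T2": denom,
        "T1NoCorr": a_nc,
        "T2NoCorr": denom_nc,
        "flag": np.where(usable, "", "insufficient_groups"),
    })


# ---------------------------------------------------------------------------
# Trimmed-likelihood chi-square null


_BIG = 1e30  # finite sentinel so bounded optimizers never see inf/nan


def _trunc_neg_loglik(vals, lo, hi, fst_bar, df) -> float:
    scale = fst_bar / df
    z = vals / scale
    ll = np.sum(stats.chi2.logpdf(z, df)) - len(vals) * np.log(scale)
    if lo > 0 or np.isfinite(hi):
        norm = stats.chi2.cdf(hi / scale, df) - stats.chi2.cdf(lo / scale, df)
        if norm <= 0:
            return _BIG
        ll -= len(vals) * np.log(norm)
    if not np.isfinite(ll):
        return _BIG
    return -ll


def fit_trimmed_chisq(
    fst_table: pd.DataFrame,
    trim_low: float = 0.05,
    trim_high: float = 0.05,
    he_min: float = 0.1,
    df_bounds: tuple[float, float] = (0.5, 500.0),
) -> ChiSqFit:
    """Infer the neutral null FstNoCorr ~ (FSTbar/df) chi2_df by trimmed ML.

    Keeps loci with He >= he_min and positive uncorrected Fst, drops the
    lowest ``trim_low`` and highest ``trim_high`` quantiles, and fits the
    truncated scaled chi-square to the retained interval by nested
    bounded 1-D optimization (profile over df, inner over FSTbar).
    """
    ok = (fst_table["flag"] == "") & (fst_table["He"] >= he_min)
    vals = fst_table.loc[ok, "FstNoCorr"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals) & (vals > 0)]
    if len(vals) < 100:
        raise OutflankError(
            f"only {len(vals)} usable loci after the He filter; need >= 100")
    vals = np.sort(vals)
    n = len(vals)
    i_lo = int(np.floor(n * trim_low))
    i_hi = n - int(np.floor(n * trim_high))
    kept = vals[i_lo:i_hi]
    if trim_low > 0 or trim_high > 0:
        lo, hi = float(kept.min()), float(kept.max())
    else:
        lo, hi = 0.0, np.inf

    def profile(log_df):
        df = np.exp(log_df)
        inner = optimize.minimize_scalar(
            lambda log_fbar: _trunc_neg_loglik(
                kept, lo, hi, np.exp(log_fbar), df),
            bounds=(np.log(1e-6), np.log(1.0)), method="bounded",
            options={"xatol": 1e-8})
        return inner.fun, np.exp(inner.x)

    res = optimize.minimize_scalar(
        lambda ld: profile(ld)[0],
        bounds=(np.log(df_bounds[0]), np.log(df_bounds[1])),
        method="bounded", options={"xatol": 1e-7})
    df_hat = float(np.exp(res.x))
    nll, fbar_hat = profile(res.x)
    at_bound = (
        df_hat <= df_bounds[0] * 1.01 or df_hat >= df_bounds[1] * 0.99
        or fbar_hat <= 1.1e-6 or fbar_hat >= 0.99)
    return ChiSqFit(
        df_inferred=df_hat,
        fst_bar=float(fbar_hat),
        trim_low=trim_low,
        trim_high=trim_high,
        he_min=he_min,
        n_loci_used=len(kept),
        truncation=(lo, hi if np.isfinite(hi) else float("inf")),
        loglik=float(-nll),
        at_bound=at_bound,
    )


def outlier_pvalues(fst_table: pd.DataFrame, fit: ChiSqFit,
                    q_threshold: float = 0.05) -> pd.DataFrame:
    """Right-tail p and BH q-values from the fitted null, He-filtered."""
    from statsmodels.stats.multitest import multipletests

    out = fst_table.copy()
    x = out["FstNoCorr"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        p = stats.chi2.sf(x * fit.df_inferred / fit.fst_bar, fit.df_inferred)
    p = np.where(np.isfinite(x) & (x > 0), p, 1.0)
    p = np.where(out["flag"] == "", p, np.nan)
    out["p_right"] = p
    testable = (out["flag"] == "") & (out["He"] >= fit.he_min) & np.isfinite(p)
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]
    out["q"] = q
    out["outlier"] = (out["q"] < q_threshold).fillna(False)
    return out


def outlier_test(
    panel: GenotypePanel,
    group_labels,
    exclude_chromosomes=(SEX_CHROMOSOME,),
    trim_low: float = 0.05,
    trim_high: float = 0.05,
    he_min: float = 0.1,
    q_threshold: float = 0.05,
) -> dict[str, OutlierScan]:
    """Full outlier scan per grouping, sex chromosome excluded.

    ``group_labels`` is either one label vector or a mapping of grouping
    name (e.g. ``location``, ``basin``) to label vector; each grouping is
    scanned independently and reported separately.
    """
    if not isinstance(group_labels, dict):
        group_labels = {"groups": group_labels}
    work = panel.drop_chromosomes(exclude_chromosomes or ())
    if work.n_snps == 0:
        raise OutflankError("no loci left after chromosome exclusion")
    results = {}
    for name, labels in group_labels.items():
        labels = np.asarray(labels)
        if len(pd.unique(labels)) < 2:
            raise OutflankError(
                f"grouping {name!r} has a single group; Fst undefined")
        fst = per_locus_fst(work, labels)
        fit = fit_trimmed_chisq(
            fst, trim_low=trim_low, trim_high=trim_high, he_min=he_min)
        table = outlier_pvalues(fst, fit, q_threshold=q_threshold)
        results[name] = OutlierScan(
            grouping=name,
            fst_table=table,
            fit=fit,
            n_outliers=int(table["outlier"].sum()),
        )
    return results
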