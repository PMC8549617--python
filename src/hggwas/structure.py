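"""Population structure: kinship, PCA, pairwise Fst, genetic sex.

The kinship matrix is the Gram matrix of standardized genotypes,
K = X X' / 2n with n the number of SNPs; its eigenvectors are the
principal components used to visualize basin-level structure and to
recover the male/female split driven by the sex chromosome.  Pairwise
Fst between sampling locations follows the kinship-based route of the
popkin estimator: a raw moment matrix of dosages, re-anchored at the
between-population mean, whose rescaled self-kinship terms average to
the pair's Fst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .genotype_io import MISSING, GenotypePanel, StandardizedGenotypes


class StructureError(ValueError):
    pass


class NoSexSignalError(StructureError):
    """No principal component correlates with phenotypic sex."""


@dataclass
class KinshipMatrix:
    K: np.ndarray
    n_snps: int
    sample_ids: pd.Series

    def __post_init__(self) -> None:
        asym = np.abs(self.K - self.K.T).max()
        if asym > 1e-10:
            raise StructureError(f"kinship matrix asymmetric (max dev {asym:g})")


@dataclass
class PCADecomposition:
    eigenvalues: np.ndarray   # descending
    components: np.ndarray    # eigenvectors in columns, unit norm
    sample_ids: pd.Series

    def scores(self, k: int | None = None) -> pd.DataFrame:
        k = k or self.components.shape[1]
        return pd.DataFrame(
            self.components[:, :k],
            columns=[f"PC{i + 1}" for i in range(k)],
            index=self.sample_ids.to_numpy(),
        )


@dataclass
class SexAssignment:
    pc_index: int                  # 0-based index of the sex-separating PC
    labels: np.ndarray             # "M"/"F" per individual
    cluster_centers: tuple[float, float]
    chi2: float
    p_value: float
    point_biserial: float          # correlation of the chosen PC with known sex


def compute_kinship(std: StandardizedGenotypes) -> KinshipMatrix:
    """K = X X' / (2 M) over the M standardized SNP columns."""
    if std.n_snps == 0:
        raise StructureError("no SNP columns to build a kinship matrix from")
    X = std.X
    K = X @ X.T / (2 * std.n_snps)
    K = (K + K.T) / 2  # enforce exact symmetry against rounding
    return KinshipMatrix(K=K, n_snps=std.n_snps, sample_ids=std.sample_ids)


def compute_pca(kinship: KinshipMatrix) -> PCADecomposition:
    """Full eigendecomposition of K, eigenvalues descending.

    Sign convention: the largest-magnitude loading of each eigenvector is
    made positive so repeated runs produce identical component signs.
    """
    vals, vecs = linalg.eigh(kinship.K)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    flip = vecs[np.abs(vecs).argmax(axis=0), np.arange(vecs.shape[1])] < 0
    vecs[:, flip] *= -1
    return PCADecomposition(
        eigenvalues=vals, components=vecs, sample_ids=kinship.sample_ids)


# ---------------------------------------------------------------------------
# Pairwise Fst (popkin-style moment estimator)


def _raw_moment_matrix(panel: GenotypePanel) -> np.ndarray:
    """A_jk = mean over co-observed loci of (x_j - 1)(x_k - 1)."""
    obs = (panel.dosages != MISSING).astype(float)
    xc = np.where(panel.dosages == MISSING, 0.0, panel.dosages - 1.0)
    pair_counts = obs @ obs.T
    if (pair_counts == 0).any():
        raise StructureError("a pair of individuals shares no observed locus")
    return (xc @ xc.T) / pair_counts


def popkin_pairwise_fst(panel: GenotypePanel, group_labels) -> pd.DataFrame:
    """Pairwise Fst matrix between populations via the kinship route.

    For each pair of populations the moment matrix restricted to the pair
    is re-anchored at its between-population mean (the most distant
    admissible pair), converted to kinship, and the pair's Fst is the
    group-balanced mean of the implied self-kinship (inbreeding)
    coefficients, clipped to [0, 1].
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != panel.n_individuals:
        raise StructureError("one group label per individual required")
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise StructureError("need at least 2 groups for pairwise Fst")
    members = {g: np.flatnonzero(labels == g) for g in groups}
    for g, idx in members.items():
        if len(idx) < 2:
            raise StructureError(f"group {g!r} has fewer than 2 members")

    A = _raw_moment_matrix(panel)
    out = pd.DataFrame(0.0, index=groups, columns=groups)
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            ia, ib = members[groups[a]], members[groups[b]]
            between = A[np.ix_(ia, ib)].mean()
            denom = 1.0 - between
            if denom <= 0:
                fst = 1.0
            else:
                diag = np.concatenate([A[ia, ia], A[ib, ib]])
                phi_self = (diag - between) / denom
                inbreeding = 2 * phi_self - 1
                # balanced weighting: each population contributes 1/2
                f_a = inbreeding[: len(ia)].mean()
                f_b = inbreeding[len(ia):].mean()
                fst = float(np.clip((f_a + f_b) / 2, 0.0, 1.0))
            out.iloc[a, b] = out.iloc[b, a] = fst
    return out


# ---------------------------------------------------------------------------
# Genetic sex


def _two_means_1d(x: np.ndarray, max_iter: int = 100) -> tuple[np.ndarray, tuple[float, float]]:
    """Deterministic 1-D 2-means: centers start at the 10th/90th percentiles;
    ties assign to the lower-center cluster."""
    c_lo, c_hi = np.percentile(x, 10), np.percentile(x, 90)
    if c_lo == c_hi:
        raise StructureError("degenerate PC scores: all values identical")
    assign = np.zeros(len(x), dtype=int)
    for it in range(max_iter):
        d_lo, d_hi = np.abs(x - c_lo), np.abs(x - c_hi)
        new = (d_hi < d_lo).astype(int)  # ties -> lower-center cluster
        if (new == assign).all() and it > 0:
            break
        assign = new
        if assign.all() or not assign.any():
            break
        c_lo, c_hi = x[assign == 0].mean(), x[assign == 1].mean()
    return assign, (float(c_lo), float(c_hi))


def assign_genetic_sex(
    pca: PCADecomposition,
    known_sex,
    n_pcs: int = 10,
    min_abs_corr: float = 0.5,
) -> SexAssignment:
    """Assign a genetic sex to every individual from PC clustering.

    Among the first ``n_pcs`` components, pick the one most correlated
    (point-biserial) with known phenotypic sex, split all individuals by
    1-D 2-means on that component, and map clusters to sexes by majority
    of the known labels.  Agreement between clusters and known sex is
    reported as a plain (uncorrected) Pearson chi-square.
    """
    known = np.asarray(known_sex, dtype=object)
    known = np.where(pd.isna(known), "", known).astype(str)
    is_known = np.isin(known, ("M", "F"))
    if len(np.unique(known[is_known])) < 2:
        raise StructureError("need known individuals of both sexes")
    y = (known[is_known] == "M").astype(float)

    n_pcs = min(n_pcs, pca.components.shape[1])
    corrs = np.array([
        np.corrcoef(pca.components[is_known, i], y)[0, 1]
        if np.std(pca.components[is_known, i]) > 0 else 0.0
        for i in range(n_pcs)
    ])
    best = int(np.nanargmax(np.abs(corrs)))
    if not np.abs(corrs[best]) > min_abs_corr:
        raise NoSexSignalError(
            f"no PC among the first {n_pcs} correlates with sex "
            f"(max |r| = {np.abs(corrs).max():.3f}); the panel may lack "
            "the sex chromosome")

    scores = pca.components[:, best]
    assign, centers = _two_means_1d(scores)
    # majority vote of known labels maps cluster -> sex
    m_frac_1 = (known[is_known & (assign == 1)] == "M").mean() if (
        is_known & (assign == 1)).any() else 0.0
    m_frac_0 = (known[is_known & (assign == 0)] == "M").mean() if (
        is_known & (assign == 0)).any() else 0.0
    male_cluster = 1 if m_frac_1 >= m_frac_0 else 0
    labels = np.where(assign == male_cluster, "M", "F")

    table = pd.crosstab(assign[is_known], known[is_known])
    if table.shape == (2, 2):
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    else:  # one cluster holds all known individuals
        chi2, p = 0.0, 1.0
    return SexAssignment(
        pc_index=best,
        labels=labels,
        cluster_centers=centers,
        chi2=float(chi2),
        p_value=float(p),
        point_biserial=float(corrs[best]),
    )


# ---------------------------------------------------------------------------
# Logistic sex-association scan


def _logistic_wald(g: np.ndarray, y: np.ndarray, max_iter: int = 60):
    """Newton fit of P(male) = expit(b0 + b1 g); Wald z on b1.

    Returns (beta1, se, z, separated).  Complete separation shows up as a
    diverging coefficient; the statistic is capped and flagged.
    """
    X = np.column_stack([np.ones_like(g), g])
    beta = np.zeros(2)
    separated = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        info = X.T @ (X * w[:, None])
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta += step
        if np.abs(step).max() < 1e-10:
            break
        if np.abs(beta[1]) > 15:
            separated = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1 / (1 + np.exp(-eta))
    w = mu * (1 - mu)
    info = X.T @ (X * w[:, None])
    try:
        se = float(np.sqrt(np.linalg.inv(info)[1, 1]))
    except np.linalg.LinAlgError:
        se = np.inf
    if not np.isfinite(se) or se <= 0:
        separated = True
    if np.isfinite(se) and se > 0:
        z = beta[1] / se
    else:
        z = np.sign(beta[1]) * 30.0 if beta[1] != 0 else 30.0
    if separated:
        z = float(np.clip(z, -30, 30))
    return float(beta[1]), se, float(z), separated


def sex_association_scan(panel: GenotypePanel, sex) -> pd.DataFrame:
    """Per-SNP logistic regression of sex on dosage (sex ~ genotype).

    Missing dosages are dropped per SNP.  Monomorphic SNPs get p = 1 and
    a flag; completely separated SNPs get a capped statistic and a flag.
    Returns an association table with a row per SNP.
    """
    sex = np.asarray(sex, dtype=object).astype(str)
    y_all = (sex == "M").astype(float)
    if len(np.unique(sex[np.isin(sex, ("M", "F"))])) < 2:
        raise StructureError("both sexes must be present for the scan")
    usable = np.isin(sex, ("M", "F"))

    rows = []
    for j in range(panel.n_snps):
        d = panel.dosages[:, j]
        mask = usable & (d != MISSING)
        g, y = d[mask].astype(float), y_all[mask]
        flag = ""
        if len(np.unique(g)) < 2:
            beta, se, z, p = np.nan, np.nan, 0.0, 1.0
            flag = "monomorphic"
        else:
            beta, se, z, separated = _logistic_wald(g, y)
            p = 2 * stats.norm.sf(abs(z))
            if separated:
                flag = "separated"
        rows.append((beta, se, z, max(p, 5e-324), int(mask.sum()), flag))
    out = pd.DataFrame(
        rows, columns=["effect", "se", "stat", "p", "n", "flag"])
    out.insert(0, "pos", panel.snps["pos"].to_numpy())
    out.insert(0, "chrom", panel.snps["chrom"].to_numpy())
    out.insert(0, "snp_id", panel.snps["id"].to_numpy())
    out["neglog10p"] = -np.log10(out["p"])
    return out


def per_chromosome_median_logp(assoc: pd.DataFrame) -> pd.Series:
    """Median -log10 p per chromosome, the sex-chromosome diagnostic."""
    return assoc.groupby("chrom")["neglog10p"].median()
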