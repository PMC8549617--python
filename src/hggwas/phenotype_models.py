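"""Mercury phenotype models: length regressions, basin contrasts, Tukey.

Muscle mercury (ng/g dry weight) is square-root transformed once, then
modelled with a location-specific length slope (growth rates, and hence
the length-age relation, differ between locations).  A nested F-test
asks whether per-location sediment mercury explains additional variance.
Basin-level differences use a mixed model with the basin fixed effect
and a random location intercept, summarized through two orthogonal
contrasts, plus a one-way ANOVA with Tukey HSD on sediment mercury.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lmm_gwas import fit_random_intercept_lmm

REQUIRED_COLUMNS = (
    "sample_id", "location", "basin", "hg_muscle_ng_g_dw",
    "length_mm", "sex", "hg_sediment_ug_kg_ds",
)


class PhenotypeError(ValueError):
    pass


@dataclass
class PhenotypeTable:
    """Validated per-individual phenotype records."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise PhenotypeError(f"phenotype table lacks column {col!r}")
        if (df["hg_muscle_ng_g_dw"] <= 0).any():
            raise PhenotypeError("muscle mercury must be positive (ng/g DW)")
        if (df["length_mm"] <= 0).any():
            raise PhenotypeError("length must be positive (mm)")
        loc_basin = df.groupby("location")["basin"].nunique()
        if (loc_basin > 1).any():
            bad = loc_basin[loc_basin > 1].index[0]
            raise PhenotypeError(f"location {bad!r} maps to multiple basins")
        sed = df.groupby("location")["hg_sediment_ug_kg_ds"].nunique()
        if (sed > 1).any():
            bad = sed[sed > 1].index[0]
            raise PhenotypeError(
                f"sediment mercury varies within location {bad!r}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t", keep_default_na=False,
                               na_values=[]))

    @property
    def sqrt_hg(self) -> np.ndarray:
        return np.sqrt(self.df["hg_muscle_ng_g_dw"].to_numpy(dtype=float))

    def per_location_sediment(self) -> pd.DataFrame:
        return (self.df.groupby("location")
                .agg(basin=("basin", "first"),
                     hg_sediment_ug_kg_ds=("hg_sediment_ug_kg_ds", "first"))
                .reset_index())


def _length_design(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Global intercept plus one length slope per location."""
    locs = pd.unique(df["location"])
    length = df["length_mm"].to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for loc in locs:
        cols.append(np.where(df["location"] == loc, length, 0.0))
        names.append(f"length:{loc}")
    return np.column_stack(cols), names


def fit_length_sediment_models(pheno: PhenotypeTable) -> dict:
    """Nested OLS comparison of the length model vs length + sediment.

    Model 1: sqrt(Hg) ~ location:length (per-location length slopes).
    Model 2: model 1 + per-location sediment mercury.  The models are
    compared with a 1-df F-test.  Reports adjusted R^2, per-location
    slopes with t-tests, and the sediment coefficient.
    """
    df = pheno.df
    counts = df.groupby("location").size()
    if len(counts) < 2 or (counts < 3).any():
        raise PhenotypeError(
            "need >= 2 locations with >= 3 individuals each")
    y = pheno.sqrt_hg
    X1, names1 = _length_design(df)
    sediment = df["hg_sediment_ug_kg_ds"].to_numpy(dtype=float)
    if np.ptp(sediment) == 0:
        raise PhenotypeError(
            "sediment mercury is constant across locations; the nested "
            "comparison is undefined")
    m1 = sm.OLS(y, pd.DataFrame(X1, columns=names1)).fit()
    X2 = pd.DataFrame(np.column_stack([X1, sediment]),
                      columns=names1 + ["sediment"])
    m2 = sm.OLS(y, X2).fit()
    f_stat, f_p, df_diff = m2.compare_f_test(m1)
    slopes = pd.DataFrame({
        "term": names1[1:],
        "estimate": m1.params.iloc[1:].to_numpy(),
        "se": m1.bse.iloc[1:].to_numpy(),
        "t": m1.tvalues.iloc[1:].to_numpy(),
        "p": m1.pvalues.iloc[1:].to_numpy(),
    })
    return {
        "model1_adj_r2": float(m1.rsquared_adj),
        "model2_adj_r2": float(m2.rsquared_adj),
        "model1_rss": float(m1.ssr),
        "model2_rss": float(m2.ssr),
        "f_stat": float(f_stat),
        "f_p": float(f_p),
        "df_diff": float(df_diff),
        "sediment_coef": float(m2.params["sediment"]),
        "sediment_p": float(m2.pvalues["sediment"]),
        "per_location_slopes": slopes,
        "transform": "sqrt",
    }


def _orthogonal_contrast_design(basins: np.ndarray, basin_order: list[str]):
    """Columns whose coefficients estimate c1'mu and c2'mu directly.

    c1 compares the first basin with the mean of the other two
    (1, -1/2, -1/2); c2 compares the second with the third (0, 1, -1).
    The coding matrix is C (C'C)^-1 so each fitted coefficient equals the
    corresponding contrast of basin means.
    """
    C = np.array([[1.0, 0.0], [-0.5, 1.0], [-0.5, -1.0]])
    coding = C @ np.linalg.inv(C.T @ C)
    idx = np.array([basin_order.index(b) for b in basins])
    return coding[idx], C


def tukey_hsd(values, groups) -> pd.DataFrame:
    """All-pairs Tukey honest-significant-difference test.

    Adjusted p-values come from the studentized range distribution with
    k groups and N - k error degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    k = len(levels)
    if k < 2:
        raise PhenotypeError("Tukey HSD needs at least 2 groups")
    ns = np.array([(groups == g).sum() for g in levels])
    means = np.array([values[groups == g].mean() for g in levels])
    dfe = len(values) - k
    mse = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum()
              for g in levels) / dfe
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[j] - means[i]
            se = np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, dfe))
            rows.append((levels[i], levels[j], diff, se, q, p_adj))
    return pd.DataFrame(
        rows, columns=["group1", "group2", "meandiff", "se", "q", "p_adj"])


def basin_effects_anova(
    pheno: PhenotypeTable,
    basin_order: list[str] | None = None,
) -> dict:
    """Basin effects on muscle and sediment mercury.

    Muscle: mixed model sqrt(Hg) ~ basin + location:length + (1|location)
    with orthogonal basin contrasts (first basin vs mean of the other
    two; second vs third).  Sediment: one-way ANOVA of sqrt(sediment Hg)
    over basins at the location level, with Tukey HSD pairwise tests.
    """
    df = pheno.df
    basins = pd.unique(df["basin"])
    if len(basins) != 3:
        raise PhenotypeError("basin contrasts require exactly 3 basins")
    basin_order = basin_order or sorted(basins)
    locs_per_basin = df.groupby("basin")["location"].nunique()
    if (locs_per_basin < 2).any():
        warnings.warn(
            "a basin contains a single location; the random-intercept "
            "variance is weakly identified", stacklevel=2)

    y = pheno.sqrt_hg
    contrast_cols, _ = _orthogonal_contrast_design(
        df["basin"].to_numpy(), basin_order)
    X_len, names_len = _length_design(df)
    X = pd.DataFrame(
        np.column_stack([X_len[:, :1], contrast_cols, X_len[:, 1:]]),
        columns=["intercept", "contrast1", "contrast2"] + names_len[1:])
    fit = fit_random_intercept_lmm(y, X, df["location"].to_numpy())

    sed = pheno.per_location_sediment()
    sqrt_sed = np.sqrt(sed["hg_sediment_ug_kg_ds"].to_numpy(dtype=float))
    groups = [sqrt_sed[sed["basin"] == b] for b in basin_order]
    f_stat, f_p = stats.f_oneway(*groups)
    tukey = tukey_hsd(sqrt_sed, sed["basin"].to_numpy())

    return {
        "basin_order": list(basin_order),
        "contrast1": float(fit.params["contrast1"]),
        "contrast1_se": float(fit.bse["contrast1"]),
        "contrast1_p": float(fit.pvalues["contrast1"]),
        "contrast2": float(fit.params["contrast2"]),
        "contrast2_se": float(fit.bse["contrast2"]),
        "contrast2_p": float(fit.pvalues["contrast2"]),
        "lmm_sigma2_location": fit.sigma2_b,
        "lmm_sigma2_residual": fit.sigma2_e,
        "sediment_f": float(f_stat),
        "sediment_p": float(f_p),
        "sediment_tukey": tukey,
        "transform": "sqrt",
    }
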