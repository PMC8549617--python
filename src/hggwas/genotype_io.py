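"""Genotype input, quality control and standardization.

Genotypes are biallelic SNP dosages: the count of alternate alleles in a
diploid genotype (0, 1 or 2), with a sentinel for missing calls.  Quality
control mirrors a typical genotyping-by-sequencing pipeline: drop
non-biallelic records, then SNPs with a high failed-genotyping rate, then
individuals with too much of their genome missing.  Downstream analyses
operate on the z-scored, mean-imputed dosage matrix ``X``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing dosage; distinct from the valid values {0, 1, 2}.
MISSING: int = -1

#: Stickleback chromosome naming convention; groupXIX carries the
#: sex-determining region.
SEX_CHROMOSOME: str = "groupXIX"

_ROMAN = [
    (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def roman_numeral(n: int) -> str:
    """Roman numeral for a small positive integer (chromosome naming)."""
    if n <= 0:
        raise ValueError("roman numerals start at 1")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def chromosome_names(n: int = 21) -> list[str]:
    """``groupI`` ... ``groupXXI`` style chromosome names."""
    return [f"group{roman_numeral(i)}" for i in range(1, n + 1)]


class GenotypeIOError(ValueError):
    """Problem reading or validating genotype data."""


class EmptyPanelError(GenotypeIOError):
    """All SNPs or all individuals were removed."""


@dataclass
class GenotypePanel:
    """Dosage matrix plus SNP and sample metadata.

    Parameters
    ----------
    dosages
        ``N x M`` integer array of alternate-allele counts; ``MISSING``
        marks failed genotypes.
    snps
        Per-SNP records with columns ``chrom, pos, id, ref, alt`` (``alt``
        is a comma-joined list for multiallelic records).
    samples
        Per-individual records with columns ``id, location, basin``.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise GenotypeIOError(
                f"{len(self.samples)} sample records for {n} dosage rows")
        if len(self.snps) != m:
            raise GenotypeIOError(
                f"{len(self.snps)} SNP records for {m} dosage columns")
        valid = np.isin(self.dosages, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise GenotypeIOError(
                f"invalid dosage {self.dosages[tuple(bad)]} at "
                f"sample {bad[0]}, SNP {bad[1]}")
        if self.snps["id"].duplicated().any():
            dup = self.snps["id"][self.snps["id"].duplicated()].iloc[0]
            raise GenotypeIOError(f"duplicate SNP id {dup!r}")
        if self.samples["id"].duplicated().any():
            dup = self.samples["id"][self.samples["id"].duplicated()].iloc[0]
            raise GenotypeIOError(f"duplicate sample id {dup!r}")
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def is_biallelic(self) -> np.ndarray:
        alt = self.snps["alt"].astype(str)
        return ((alt != ".") & (alt != "") & ~alt.str.contains(",")).to_numpy()

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypePanel":
        """Panel restricted to the given sample/SNP integer indices."""
        si = np.arange(self.n_individuals) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypePanel(
            dosages=self.dosages[np.ix_(si, vi)],
            snps=self.snps.iloc[vi].reset_index(drop=True),
            samples=self.samples.iloc[si].reset_index(drop=True),
        )

    def drop_chromosomes(self, chromosomes) -> "GenotypePanel":
        keep = ~self.snps["chrom"].isin(list(chromosomes)).to_numpy()
        return self.subset(snp_idx=np.flatnonzero(keep))


@dataclass
class StandardizedGenotypes:
    """z-scored, mean-imputed dosage matrix.

    Each retained SNP column has mean 0 and sample variance 1 over the
    originally observed entries; originally missing entries are exactly 0
    (the mean z-score).  Monomorphic columns are dropped, not kept as NaN.
    """

    X: np.ndarray
    snps: pd.DataFrame
    sample_ids: pd.Series
    means: np.ndarray
    sds: np.ndarray
    dropped_monomorphic: list = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# Reading


def read_vcf(path, sample_metadata: pd.DataFrame | None = None) -> GenotypePanel:
    """Read genotypes from a VCF (v4.x, plain or bgzipped) with GT fields.

    Dosage is the count of non-reference alleles in the genotype;
    ``./.`` becomes missing.  Multiallelic records are retained with their
    full alternate-allele list (the biallelic filter runs later, in
    :func:`apply_qc_filters`).  Sample order follows the VCF header.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise GenotypeIOError(f"cannot open VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise EmptyPanelError(f"VCF {path} declares no samples")

    rows = []
    cols = []
    record_no = 0
    try:
        for var in vcf:
            record_no += 1
            alts = var.ALT or []
            if len(alts) <= 1:
                gt = var.gt_types.astype(np.int8)  # 0/1/2, 3 = unknown
                gt[gt == 3] = MISSING
            else:
                gt = np.empty(len(sample_ids), dtype=np.int8)
                for i, call in enumerate(var.genotypes):
                    alleles = call[:-1]
                    if any(a < 0 for a in alleles):
                        gt[i] = MISSING
                    else:
                        gt[i] = sum(1 for a in alleles if a > 0)
            cols.append(gt)
            rows.append((
                var.CHROM,
                int(var.POS),
                var.ID if var.ID else f"{var.CHROM}_{var.POS}",
                var.REF,
                ",".join(alts) if alts else ".",
            ))
    except GenotypeIOError:
        raise
    except Exception as exc:
        raise GenotypeIOError(
            f"malformed VCF record near data line {record_no + 1} "
            f"of {path}: {exc}") from exc
    if not rows:
        raise EmptyPanelError(f"VCF {path} contains no variant records")

    snps = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    if sample_metadata is not None:
        meta = sample_metadata.set_index("id").reindex(sample_ids)
        samples = pd.DataFrame({
            "id": sample_ids,
            "location": meta["location"].fillna("").to_numpy(),
            "basin": meta["basin"].fillna("").to_numpy(),
        })
    else:
        samples = pd.DataFrame(
            {"id": sample_ids, "location": "", "basin": ""})
    return GenotypePanel(
        dosages=np.column_stack(cols).astype(np.int8),
        snps=snps,
        samples=samples,
    )


def read_dosage_table(path, sample_metadata: pd.DataFrame | None = None) -> GenotypePanel:
    """Read a plain TSV dosage matrix.

    Rows are SNPs with columns ``chrom, pos, id`` followed by one dosage
    column per sample; ``NA`` marks missing genotypes.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    for col in ("chrom", "pos", "id"):
        if col not in df.columns:
            raise GenotypeIOError(f"dosage table {path} lacks column {col!r}")
    sample_ids = [c for c in df.columns if c not in ("chrom", "pos", "id")]
    if not sample_ids:
        raise EmptyPanelError(f"dosage table {path} has no sample columns")
    dos = df[sample_ids].to_numpy(dtype=float).T
    dosages = np.where(np.isnan(dos), MISSING, dos).astype(np.int8)
    snps = pd.DataFrame({
        "chrom": df["chrom"], "pos": df["pos"].astype(int), "id": df["id"],
        "ref": "A", "alt": "G",
    })
    if sample_metadata is not None:
        meta = sample_metadata.set_index("id").reindex(sample_ids)
        samples = pd.DataFrame({
            "id": sample_ids,
            "location": meta["location"].fillna("").to_numpy(),
            "basin": meta["basin"].fillna("").to_numpy(),
        })
    else:
        samples = pd.DataFrame({"id": sample_ids, "location": "", "basin": ""})
    return GenotypePanel(dosages=dosages, snps=snps, samples=samples)


def write_dosage_table(panel: GenotypePanel, path) -> None:
    """Write the panel as a plain TSV dosage matrix (``NA`` = missing)."""
    dos = panel.dosages.astype(object).T.copy()
    dos[dos == MISSING] = "NA"
    df = pd.concat(
        [panel.snps[["chrom", "pos", "id"]],
         pd.DataFrame(dos, columns=panel.samples["id"])], axis=1)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quality control


def apply_qc_filters(
    panel: GenotypePanel,
    max_snp_missing: float = 0.10,
    max_ind_missing: float = 0.25,
) -> tuple[GenotypePanel, dict]:
    """Sequential QC: biallelic -> SNP missingness -> individual missingness.

    Missingness is recomputed after each step, so the individual filter is
    evaluated over the surviving SNPs only.  Returns the filtered panel and
    a report of how many SNPs/individuals each step removed.
    """
    if panel.n_snps == 0 or panel.n_individuals == 0:
        raise EmptyPanelError("cannot QC an empty panel")
    report = {
        "n_snps_in": panel.n_snps,
        "n_individuals_in": panel.n_individuals,
        "max_snp_missing": max_snp_missing,
        "max_ind_missing": max_ind_missing,
    }

    biallelic = panel.is_biallelic()
    report["non_biallelic_snps_removed"] = int((~biallelic).sum())
    panel = panel.subset(snp_idx=np.flatnonzero(biallelic))
    if panel.n_snps == 0:
        raise EmptyPanelError("no biallelic SNPs left after QC")

    snp_missing = panel.missing_mask.mean(axis=0)
    keep_snp = snp_missing <= max_snp_missing
    report["high_missing_snps_removed"] = int((~keep_snp).sum())
    panel = panel.subset(snp_idx=np.flatnonzero(keep_snp))
    if panel.n_snps == 0:
        raise EmptyPanelError("all SNPs exceeded the missingness threshold")

    ind_missing = panel.missing_mask.mean(axis=1)
    keep_ind = ind_missing <= max_ind_missing
    report["high_missing_individuals_removed"] = int((~keep_ind).sum())
    panel = panel.subset(sample_idx=np.flatnonzero(keep_ind))
    if panel.n_individuals == 0:
        raise EmptyPanelError(
            "all individuals exceeded the missingness threshold")

    report["n_snps_out"] = panel.n_snps
    report["n_individuals_out"] = panel.n_individuals
    return panel, report


def write_qc_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Standardization


def standardize_and_impute(panel: GenotypePanel, ddof: int = 1) -> StandardizedGenotypes:
    """z-score each SNP over its observed entries; impute missing as 0.

    The per-SNP standard deviation uses denominator ``N_obs - ddof``
    (``ddof=1``, the sample standard deviation, by default).  Columns with
    zero variance (monomorphic over observed entries) or fewer than two
    observed genotypes are dropped and reported.
    """
    if panel.n_individuals < 2:
        raise GenotypeIOError("standardization needs at least 2 individuals")
    dos = panel.dosages.astype(float)
    obs = panel.dosages != MISSING
    dos[~obs] = np.nan
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(dos, axis=0)
        sds = np.sqrt(
            np.nansum((dos - means) ** 2, axis=0)
            / np.maximum(n_obs - ddof, 1))
    keep = (n_obs >= 2) & (sds > 0)
    dropped = panel.snps["id"][~keep].tolist()
    X = (dos[:, keep] - means[keep]) / sds[keep]
    X[np.isnan(X)] = 0.0
    return StandardizedGenotypes(
        X=X,
        snps=panel.snps.loc[keep].reset_index(drop=True),
        sample_ids=panel.samples["id"].reset_index(drop=True),
        means=means[keep],
        sds=sds[keep],
        dropped_monomorphic=dropped,
    )


def write_standardized_matrix(std: StandardizedGenotypes, path) -> None:
    df = pd.DataFrame(std.X.T, columns=std.sample_ids)
    df.insert(0, "id", std.snps["id"].to_numpy())
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
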