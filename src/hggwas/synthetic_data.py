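"""Synthetic hierarchical metapopulation with genotypes and phenotypes.

The generator emulates a riverine stickleback survey: 21 sampling
locations (demes) nested in 3 drainage basins, ~25 fish per location,
a few thousand biallelic SNPs across 21 chromosomes, a phenomenological
sex chromosome, and a mercury phenotype driven by fish length within
location, sex, and one or more causal SNPs of stated standardized effect.

Allele frequencies follow a two-level Balding-Nichols hierarchy: per SNP
an ancestral frequency p0 ~ Uniform(0.05, 0.95); each basin draws its
frequency from Beta(p0(1-F_b)/F_b, (1-p0)(1-F_b)/F_b); each deme draws
from the same family around its basin frequency with parameter F_d.  The
Balding-Nichols parameterization is used because its expected Fst equals
the F parameter, which gives analytic calibration bands for the
estimators tested downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    SEX_CHROMOSOME,
    GenotypePanel,
    chromosome_names,
)

BASIN_NAMES = ("Maas", "Scheldt-E", "Scheldt-W")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic metapopulation.

    Defaults are desk-scale study conditions: the survey design (21 demes,
    3 basins, 25 fish each) at a reduced SNP count (5,000 rather than the
    ~28,000 of a full GBS panel) with differentiation tuned so the mean
    pairwise Fst between demes is ~0.2.
    """

    # survey design
    n_demes: int = 21
    demes_per_basin: int = 7
    individuals_per_deme: int = 25
    # genotypes
    n_snps: int = 5000
    f_basin: float = 0.05
    f_deme: float = 0.15
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    # sex chromosome (phenomenological XY: males near-fixed heterozygous);
    # most SNPs on the sex chromosome ride along with the sex-determining
    # region, so the default covers the bulk of that chromosome's markers
    n_sex_linked: int = 150
    male_flip_rate: float = 0.02
    female_sex_allele_freq: float = 0.05
    # causal loci: standardized per-allele effects on sqrt(mercury), in
    # phenotype-SD units; 0.24 is a realistic single-locus effect for a
    # strongly associated common variant
    causal_effects_sd: tuple[float, ...] = (0.24,)
    causal_chromosome: str = "groupIV"
    causal_ancestral_freq_range: tuple[float, float] = (0.3, 0.7)
    # phenotype (sqrt scale, sqrt(ng/g DW))
    basin_sqrt_hg_means: tuple[float, ...] = (8.0, 11.5, 10.5)
    deme_intercept_sd: float = 1.2
    length_mean_range_mm: tuple[float, float] = (38.0, 52.0)
    length_sd_mm: float = 8.0
    length_slope_mean: float = 0.06
    length_slope_sd: float = 0.02
    sex_effect: float = 0.2
    residual_sd: float = 1.0
    hg_floor: float = 0.01
    # sediment mercury per location (ug/kg DS), log-normal per basin
    sediment_meanlog: tuple[float, ...] = (
        4.094344562222101,   # log 60
        5.521460917862246,   # log 250
        5.857933154483459,   # log 350
    )
    sediment_sdlog: float = 0.8
    # missingness (completely at random), plus designated high-missingness
    # SNPs/individuals so QC filters have something to remove
    missing_rate: float = 0.02
    n_high_missing_snps: int = 100
    high_missing_snp_rate: float = 0.20
    n_high_missing_individuals: int = 3
    high_missing_individual_rate: float = 0.35
    # phenotyping
    known_sex_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.f_basin < 1 and 0 <= self.f_deme < 1):
            raise ValueError("F parameters must lie in [0, 1)")
        if self.n_demes % self.demes_per_basin:
            raise ValueError("n_demes must be a multiple of demes_per_basin")
        if self.causal_chromosome == SEX_CHROMOSOME:
            raise ValueError(
                "causal SNPs may not sit on the sex chromosome "
                f"({SEX_CHROMOSOME} is excluded from outlier scans)")
        if not all(np.isfinite(self.causal_effects_sd)):
            raise ValueError("causal effects must be finite")

    @property
    def n_basins(self) -> int:
        return self.n_demes // self.demes_per_basin

    @property
    def n_individuals(self) -> int:
        return self.n_demes * self.individuals_per_deme

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)


@dataclass
class TruthRecord:
    """Ground truth of one simulated data set, for recovery tests."""

    config: SimulationConfig
    causal_snps: pd.DataFrame      # id, chrom, pos, effect_sd, effect_raw
    sex_linked_ids: list[str]
    true_sex: np.ndarray           # "M"/"F" per individual
    deme_freqs: np.ndarray         # n_demes x n_snps
    deme_coefficients: pd.DataFrame  # location, intercept, slope, length_mean
    phenotype_sd_nominal: float
    f_basin: float
    f_deme: float

    def expected_mean_pairwise_fst(self) -> float:
        """Theoretical mean pairwise Fst over all deme pairs.

        Same-basin pairs drift F_d each from a shared basin frequency;
        cross-basin pairs compound the two levels: F_b + (1-F_b) F_d.
        """
        fd, fb = self.f_deme, self.f_basin
        d, k = self.config.n_demes, self.config.demes_per_basin
        n_pairs = d * (d - 1) / 2
        same = self.config.n_basins * k * (k - 1) / 2
        cross = n_pairs - same
        f_tot = fb + (1 - fb) * fd
        return (same * fd + cross * f_tot) / n_pairs

    def pairwise_fst_band(self, width: float = 0.05) -> tuple[float, float]:
        mu = self.expected_mean_pairwise_fst()
        return max(0.0, mu - width), mu + width

    def to_json(self) -> str:
        payload = {
            "config": dataclasses.asdict(self.config),
            "causal_snps": self.causal_snps.to_dict(orient="records"),
            "sex_linked_ids": list(self.sex_linked_ids),
            "true_sex": self.true_sex.tolist(),
            "deme_freqs": np.round(self.deme_freqs, 5).tolist(),
            "deme_coefficients": self.deme_coefficients.to_dict(orient="records"),
            "phenotype_sd_nominal": self.phenotype_sd_nominal,
            "f_basin": self.f_basin,
            "f_deme": self.f_deme,
        }
        return json.dumps(payload, sort_keys=True)


def _balding_nichols(rng, p_parent: np.ndarray, f: float) -> np.ndarray:
    """Daughter allele frequencies under the Balding-Nichols model."""
    if f == 0:
        return p_parent.copy()
    a = p_parent * (1 - f) / f
    b = (1 - p_parent) * (1 - f) / f
    return rng.beta(a, b)


def _nominal_phenotype_sd(cfg: SimulationConfig) -> float:
    """Approximate total SD of sqrt(mercury) implied by the config.

    Used to convert standardized causal effects (SD units) into raw
    sqrt-scale slopes before the data exist; the realized SD differs only
    by sampling noise.
    """
    basin_means = np.asarray(cfg.basin_sqrt_hg_means, dtype=float)
    var_basin = basin_means.var()
    var_deme = cfg.deme_intercept_sd ** 2
    var_length = (cfg.length_slope_mean ** 2 + cfg.length_slope_sd ** 2) * cfg.length_sd_mm ** 2
    var_sex = cfg.sex_effect ** 2 / 4
    v0 = var_basin + var_deme + var_length + var_sex + cfg.residual_sd ** 2
    # causal loci feed back into the total variance; 2pq within demes
    p_mid = np.mean(cfg.causal_ancestral_freq_range)
    two_pq = 2 * p_mid * (1 - p_mid) * (1 - cfg.f_deme)
    e2 = float(np.sum(np.square(cfg.causal_effects_sd))) * two_pq
    if e2 >= 1:
        raise ValueError("causal effects explain >= 100% of the variance")
    return float(np.sqrt(v0 / (1 - e2)))


def simulate_metapopulation(
    config: SimulationConfig | None = None,
) -> tuple[GenotypePanel, pd.DataFrame, TruthRecord]:
    """Simulate a genotype panel, phenotype table and its ground truth.

    All randomness flows from ``config.seed`` through a single generator,
    so identical configs give bitwise-identical output.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n_demes, m = cfg.n_demes, cfg.n_snps
    n = cfg.n_individuals

    # --- map of SNPs to chromosomes and positions
    chroms = chromosome_names(21)
    chrom_of = np.array([chroms[i % 21] for i in range(m)])
    chrom_of.sort()  # contiguous blocks in groupI..groupXXI lexical order
    # order chromosomes naturally (groupI, groupII, ..., groupXXI)
    order = np.argsort([chroms.index(c) * m + i for i, c in enumerate(chrom_of)])
    chrom_of = chrom_of[order]
    pos = np.empty(m, dtype=int)
    snp_ids = np.empty(m, dtype=object)
    counter: dict[str, int] = {}
    for j, c in enumerate(chrom_of):
        counter[c] = counter.get(c, 0) + 1
        pos[j] = counter[c] * 5000
        snp_ids[j] = f"{c}_{pos[j]}"

    sex_candidates = np.flatnonzero(chrom_of == SEX_CHROMOSOME)
    if cfg.n_sex_linked > len(sex_candidates):
        raise ValueError("more sex-linked SNPs requested than SNPs on "
                         f"{SEX_CHROMOSOME}")
    sex_idx = np.sort(rng.choice(sex_candidates, cfg.n_sex_linked, replace=False))

    causal_candidates = np.flatnonzero(chrom_of == cfg.causal_chromosome)
    if len(cfg.causal_effects_sd) > len(causal_candidates):
        raise ValueError("more causal SNPs requested than SNPs on "
                         f"{cfg.causal_chromosome}")
    causal_idx = np.sort(
        rng.choice(causal_candidates, len(cfg.causal_effects_sd), replace=False))

    # --- allele frequencies: ancestral -> basin -> deme
    lo, hi = cfg.ancestral_freq_range
    p0 = rng.uniform(lo, hi, m)
    clo, chi = cfg.causal_ancestral_freq_range
    p0[causal_idx] = rng.uniform(clo, chi, len(causal_idx))
    basin_freqs = np.stack(
        [_balding_nichols(rng, p0, cfg.f_basin) for _ in range(cfg.n_basins)])
    deme_freqs = np.stack([
        _balding_nichols(rng, basin_freqs[d // cfg.demes_per_basin], cfg.f_deme)
        for d in range(n_demes)
    ])

    # --- samples
    deme_of_ind = np.repeat(np.arange(n_demes), cfg.individuals_per_deme)
    basin_of_deme = np.repeat(np.arange(cfg.n_basins), cfg.demes_per_basin)
    locations = np.array([f"loc{d + 1:02d}" for d in range(n_demes)])
    basin_names = np.array(
        [BASIN_NAMES[b % len(BASIN_NAMES)] for b in range(cfg.n_basins)])
    sample_ids = np.array([f"fish{i + 1:04d}" for i in range(n)])

    genotypes = rng.binomial(2, deme_freqs[deme_of_ind, :]).astype(np.int8)

    # --- sex and sex-linked dosages
    true_sex = np.where(rng.random(n) < 0.5, "M", "F")
    male = true_sex == "M"
    for j in sex_idx:
        col = rng.binomial(2, cfg.female_sex_allele_freq, n).astype(np.int8)
        col[male] = 1
        flips = male & (rng.random(n) < cfg.male_flip_rate)
        col[flips] = rng.choice(np.array([0, 2], dtype=np.int8), flips.sum())
        genotypes[:, j] = col

    # --- phenotype
    sd_nominal = _nominal_phenotype_sd(cfg)
    effects_raw = np.asarray(cfg.causal_effects_sd) * sd_nominal
    basin_mean = np.asarray(cfg.basin_sqrt_hg_means, dtype=float)
    deme_intercept = (basin_mean[basin_of_deme]
                      + rng.normal(0, cfg.deme_intercept_sd, n_demes))
    deme_slope = rng.normal(cfg.length_slope_mean, cfg.length_slope_sd, n_demes)
    deme_length_mean = rng.uniform(*cfg.length_mean_range_mm, n_demes)

    length = rng.normal(deme_length_mean[deme_of_ind], cfg.length_sd_mm)
    length = np.maximum(length, 15.0)
    sqrt_hg = (deme_intercept[deme_of_ind]
               + deme_slope[deme_of_ind] * (length - deme_length_mean[deme_of_ind])
               + cfg.sex_effect * male.astype(float)
               + genotypes[:, causal_idx].astype(float) @ effects_raw
               + rng.normal(0, cfg.residual_sd, n))
    hg = np.maximum(sqrt_hg, np.sqrt(cfg.hg_floor)) ** 2

    sediment_meanlog = np.asarray(cfg.sediment_meanlog, dtype=float)
    sediment = np.exp(rng.normal(
        sediment_meanlog[basin_of_deme], cfg.sediment_sdlog))

    # --- missingness (after phenotype draws so rates don't shift them)
    miss = rng.random((n, m)) < cfg.missing_rate
    protected = np.zeros(m, dtype=bool)
    protected[sex_idx] = True
    protected[causal_idx] = True
    hm_pool = np.flatnonzero(~protected)
    hm_snps = rng.choice(hm_pool, min(cfg.n_high_missing_snps, len(hm_pool)),
                         replace=False)
    miss[:, hm_snps] |= rng.random((n, len(hm_snps))) < cfg.high_missing_snp_rate
    hm_inds = rng.choice(n, min(cfg.n_high_missing_individuals, n), replace=False)
    miss[hm_inds, :] |= (rng.random((len(hm_inds), m))
                         < cfg.high_missing_individual_rate)
    genotypes[miss] = MISSING

    # --- assemble
    panel = GenotypePanel(
        dosages=genotypes,
        snps=pd.DataFrame({
            "chrom": chrom_of, "pos": pos, "id": snp_ids,
            "ref": "A", "alt": "G",
        }),
        samples=pd.DataFrame({
            "id": sample_ids,
            "location": locations[deme_of_ind],
            "basin": basin_names[basin_of_deme[deme_of_ind]],
        }),
    )
    known = rng.random(n) < cfg.known_sex_fraction
    pheno = pd.DataFrame({
        "sample_id": sample_ids,
        "location": locations[deme_of_ind],
        "basin": basin_names[basin_of_deme[deme_of_ind]],
        "hg_muscle_ng_g_dw": hg,
        "length_mm": length,
        "sex": np.where(known, true_sex, ""),
        "hg_sediment_ug_kg_ds": sediment[deme_of_ind],
    })
    truth = TruthRecord(
        config=cfg,
        causal_snps=pd.DataFrame({
            "id": snp_ids[causal_idx],
            "chrom": chrom_of[causal_idx],
            "pos": pos[causal_idx],
            "effect_sd": np.asarray(cfg.causal_effects_sd, dtype=float),
            "effect_raw": effects_raw,
        }),
        sex_linked_ids=list(snp_ids[sex_idx]),
        true_sex=true_sex,
        deme_freqs=deme_freqs,
        deme_coefficients=pd.DataFrame({
            "location": locations,
            "intercept": deme_intercept,
            "slope": deme_slope,
            "length_mean": deme_length_mean,
        }),
        phenotype_sd_nominal=sd_nominal,
        f_basin=cfg.f_basin,
        f_deme=cfg.f_deme,
    )
    return panel, pheno, truth


# ---------------------------------------------------------------------------
# Fixture files

_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as a minimal but valid VCF v4.2 with GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.snps["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples["id"]) + "\n")
        snps = panel.snps
        for j in range(panel.n_snps):
            gts = "\t".join(_VCF_GT[int(g)] for g in panel.dosages[:, j])
            fh.write(
                f"{snps['chrom'][j]}\t{snps['pos'][j]}\t{snps['id'][j]}\t"
                f"{snps['ref'][j]}\t{snps['alt'][j]}\t.\tPASS\t.\tGT\t{gts}\n")


def write_fixture_set(
    panel: GenotypePanel,
    pheno: pd.DataFrame,
    truth: TruthRecord,
    out_dir,
) -> dict[str, Path]:
    """Write VCF + phenotype TSV + truth/config JSON; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.json",
        "config": out / "sim_config.json",
    }
    write_vcf(panel, paths["vcf"])
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False)
    paths["truth"].write_text(truth.to_json())
    paths["config"].write_text(truth.config.to_json())
    return paths
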