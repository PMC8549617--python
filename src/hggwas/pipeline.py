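"""End-to-end orchestration: QC -> structure -> sex -> models -> scans.

Stages run in the order the analyses depend on each other, fail-soft: a
stage error is recorded in the manifest with the stage name and the
remaining independent stages still run.  Every artifact is a plain TSV
or JSON file; an index with SHA-256 checksums makes re-runs comparable
bit for bit (no timestamps enter any output).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotype_io, lfmm, lmm_gwas, outflank, phenotype_models, structure
from .genotype_io import SEX_CHROMOSOME
from .synthetic_data import SimulationConfig, simulate_metapopulation


@dataclass
class PipelineConfig:
    """Inputs, thresholds and scan settings for one pipeline run."""

    out_dir: str
    vcf_path: str | None = None
    phenotype_path: str | None = None
    simulation: SimulationConfig | None = None
    max_snp_missing: float = 0.10
    max_ind_missing: float = 0.25
    threshold_m: int | None = None     # default: number of SNPs scanned
    threshold_reps: int = 10_000
    threshold_seed: int = 2027
    lfmm_factors: int = 7
    lfmm_ridge_penalty: float = 1e-5
    outflank_he_min: float = 0.1
    outflank_trim: float = 0.05
    exclude_chromosomes: tuple[str, ...] = (SEX_CHROMOSOME,)
    bonferroni_alpha: float = 0.05

    def __post_init__(self) -> None:
        has_files = self.vcf_path is not None and self.phenotype_path is not None
        if not has_files and self.simulation is None:
            raise ValueError(
                "config needs either (vcf_path, phenotype_path) or a "
                "simulation block")

    def to_json(self) -> str:
        raw = dataclasses.asdict(self)
        return json.dumps(raw, indent=2, sort_keys=True, default=str)


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    bundle: dict = field(repr=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every analysis stage, recording status per stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "parameters": json.loads(config.to_json())}
    bundle: dict = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
                manifest["stages"][name] = {"status": "ok"}
            except Exception as exc:
                manifest["stages"][name] = {
                    "status": "error",
                    "error": f"{type(exc).__name__}: {exc}",
                    "traceback": traceback.format_exc(limit=3),
                }
            return fn
        return deco

    # --- load or simulate -------------------------------------------------
    @stage("load")
    def _load():
        if config.simulation is not None:
            panel, pheno_df, truth = simulate_metapopulation(config.simulation)
            bundle["truth"] = truth
        else:
            pheno_df = pd.read_csv(
                config.phenotype_path, sep="\t", keep_default_na=False,
                na_values=[])
            meta = pheno_df.rename(columns={"sample_id": "id"})[
                ["id", "location", "basin"]]
            panel = genotype_io.read_vcf(config.vcf_path, sample_metadata=meta)
        bundle["panel_raw"] = panel
        bundle["pheno_df"] = pheno_df
        missing = set(panel.samples["id"]) - set(pheno_df["sample_id"])
        if missing:
            raise phenotype_models.PhenotypeError(
                "phenotype table lacks sample(s): "
                + ", ".join(sorted(missing)[:5]))

    if "panel_raw" not in bundle:
        return _finalize(out, manifest, bundle)

    @stage("qc")
    def _qc():
        panel, report = genotype_io.apply_qc_filters(
            bundle["panel_raw"], config.max_snp_missing, config.max_ind_missing)
        keep = bundle["pheno_df"]["sample_id"].isin(panel.samples["id"])
        bundle["panel"] = panel
        bundle["pheno"] = phenotype_models.PhenotypeTable(
            bundle["pheno_df"][keep].set_index("sample_id")
            .reindex(panel.samples["id"].to_numpy()).reset_index(
                names="sample_id"))
        bundle["qc_report"] = report
        genotype_io.write_qc_report(report, out / "qc_report.json")

    if "panel" not in bundle:
        return _finalize(out, manifest, bundle)
    panel = bundle["panel"]

    @stage("standardize")
    def _standardize():
        bundle["std_all"] = genotype_io.standardize_and_impute(panel)
        bundle["std_autosomes"] = genotype_io.standardize_and_impute(
            panel.drop_chromosomes(config.exclude_chromosomes))

    @stage("structure")
    def _structure():
        for tag, key in (("all", "std_all"), ("autosomes", "std_autosomes")):
            kin = structure.compute_kinship(bundle[key])
            pca = structure.compute_pca(kin)
            bundle[f"kinship_{tag}"] = kin
            bundle[f"pca_{tag}"] = pca
            _write_tsv(
                pca.scores(10).reset_index(names="sample_id"),
                out / f"pca_scores_{tag}.tsv")
        fst = structure.popkin_pairwise_fst(
            panel, panel.samples["location"].to_numpy())
        bundle["pairwise_fst"] = fst
        fst.to_csv(out / "pairwise_fst_locations.tsv", sep="\t",
                   float_format="%.10g")

    @stage("genetic_sex")
    def _sex():
        assignment = structure.assign_genetic_sex(
            bundle["pca_all"], bundle["pheno"].df["sex"].to_numpy())
        bundle["sex_assignment"] = assignment
        _write_tsv(pd.DataFrame({
            "sample_id": panel.samples["id"],
            "phenotypic_sex": bundle["pheno"].df["sex"],
            "genetic_sex": assignment.labels,
        }), out / "genetic_sex.tsv")

    @stage("sex_scan")
    def _sex_scan():
        sex = (bundle["sex_assignment"].labels
               if "sex_assignment" in bundle
               else bundle["pheno"].df["sex"].to_numpy())
        scan = structure.sex_association_scan(panel, sex)
        bundle["sex_scan"] = scan
        _write_tsv(scan, out / "sex_association.tsv")

    @stage("phenotype_models")
    def _pheno_models():
        rep1 = phenotype_models.fit_length_sediment_models(bundle["pheno"])
        rep2 = phenotype_models.basin_effects_anova(bundle["pheno"])
        bundle["length_sediment"] = rep1
        bundle["basin_effects"] = rep2
        serializable = {}
        for name, rep in (("length_sediment", rep1), ("basin_effects", rep2)):
            serializable[name] = {
                k: (v.to_dict(orient="records") if isinstance(v, pd.DataFrame)
                    else v)
                for k, v in rep.items()}
        (out / "phenotype_models.json").write_text(
            json.dumps(serializable, indent=2, sort_keys=True))

    @stage("lmm_scan")
    def _scan():
        if "sex_assignment" not in bundle:
            raise lmm_gwas.LmmError("genetic sex unavailable; scan skipped")
        assoc = lmm_gwas.gwas_scan(
            panel, bundle["pheno"].df, bundle["sex_assignment"].labels)
        bundle["assoc"] = assoc
        _write_tsv(assoc, out / "lmm_assoc.tsv")

    @stage("thresholds")
    def _thresholds():
        m = config.threshold_m or panel.n_snps
        null = lmm_gwas.simulate_max_logp_null(
            m, reps=config.threshold_reps, seed=config.threshold_seed)
        bonf_p, bonf_logp = lmm_gwas.bonferroni_threshold(
            config.bonferroni_alpha, m)
        bundle["thresholds"] = null
        bundle["bonferroni"] = (bonf_p, bonf_logp)
        _write_tsv(pd.DataFrame({
            "name": ["simulated_median", "simulated_q95", "bonferroni"],
            "neglog10p": [null.median, null.q95, bonf_logp],
        }), out / "thresholds.tsv")

    @stage("lfmm")
    def _lfmm():
        if "sex_assignment" not in bundle:
            raise lfmm.LfmmError("genetic sex unavailable; LFMM skipped")
        df = bundle["pheno"].df
        X = pd.DataFrame({
            "sqrt_hg_muscle": np.sqrt(df["hg_muscle_ng_g_dw"]),
            "hg_sediment": df["hg_sediment_ug_kg_ds"],
            "sexM": (bundle["sex_assignment"].labels == "M").astype(float),
            "length_mm": df["length_mm"],
        })
        std = bundle["std_all"]
        model = lfmm.fit_latent_factor_ridge(
            std, X, n_factors=config.lfmm_factors,
            ridge_penalty=config.lfmm_ridge_penalty)
        tests = lfmm.lfmm_association_test(
            model, std, X, target="sqrt_hg_muscle",
            snp_ids=std.snps["id"].to_numpy())
        bundle["lfmm_model"] = model
        bundle["lfmm_tests"] = tests
        _write_tsv(tests.table, out / "lfmm_assoc.tsv")

    @stage("outliers")
    def _outliers():
        groupings = {
            "location": panel.samples["location"].to_numpy(),
            "basin": panel.samples["basin"].to_numpy(),
        }
        scans = outflank.outlier_test(
            panel, groupings,
            exclude_chromosomes=config.exclude_chromosomes,
            trim_low=config.outflank_trim, trim_high=config.outflank_trim,
            he_min=config.outflank_he_min)
        bundle["outliers"] = scans
        for name, scan in scans.items():
            _write_tsv(scan.fst_table, out / f"outliers_{name}.tsv")

    return _finalize(out, manifest, bundle)


def _finalize(out: Path, manifest: dict, bundle: dict) -> PipelineResult:
    result = PipelineResult(out_dir=out, manifest=manifest, bundle=bundle)
    export_report(result)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return result


def export_report(result: PipelineResult) -> dict:
    """Write plot-ready data files and the checksum index.

    Manhattan data carry the chromosome, position and -log10 p of each
    SNP with the threshold lines; logQQ data pair the sorted observed
    -log10 p with the uniform expectation -log10((i - 0.5) / M).
    """
    out, bundle = result.out_dir, result.bundle
    if "assoc" in bundle:
        assoc = bundle["assoc"]
        man = assoc[["chrom", "pos", "neglog10p"]].copy()
        if "thresholds" in bundle:
            null = bundle["thresholds"]
            man["threshold_median"] = null.median
            man["threshold_q95"] = null.q95
            man["threshold_bonferroni"] = bundle["bonferroni"][1]
        _write_tsv(man, out / "manhattan.tsv")
        obs = np.sort(assoc["neglog10p"].to_numpy())[::-1]
        m = len(obs)
        expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
        _write_tsv(pd.DataFrame({
            "expected_neglog10p": expected,
            "observed_neglog10p": obs,
        }), out / "logqq.tsv")
    if "kinship_autosomes" in bundle:
        kin = bundle["kinship_autosomes"]
        pd.DataFrame(kin.K, index=kin.sample_ids.to_numpy(),
                     columns=kin.sample_ids.to_numpy()).to_csv(
            out / "kinship_autosomes.tsv", sep="\t", float_format="%.10g")
    index = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "index.json"
    }
    (out / "index.json").write_text(
        json.dumps(index, indent=2, sort_keys=True))
    return index
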