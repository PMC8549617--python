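"""Shared fixtures: one full-size synthetic study, computed once."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import hggwas as h


@pytest.fixture(scope="session")
def default_study():
    """Default synthetic metapopulation, QC'd and structured.

    Returns a dict with the raw and QC'd panel, aligned phenotypes,
    standardized matrices (with and without the sex chromosome), PCA,
    genetic sex assignment and the simulation truth.
    """
    panel_raw, pheno_raw, truth = h.simulate_metapopulation(
        h.SimulationConfig(seed=1))
    panel, qc_report = h.apply_qc_filters(panel_raw)
    keep = pheno_raw["sample_id"].isin(panel.samples["id"]).to_numpy()
    pheno = pheno_raw[keep].reset_index(drop=True)
    std_all = h.standardize_and_impute(panel)
    std_auto = h.standardize_and_impute(
        panel.drop_chromosomes([h.SEX_CHROMOSOME]))
    pca_all = h.compute_pca(h.compute_kinship(std_all))
    pca_auto = h.compute_pca(h.compute_kinship(std_auto))
    sex = h.assign_genetic_sex(pca_all, pheno["sex"].to_numpy())
    return {
        "panel_raw": panel_raw,
        "pheno_raw": pheno_raw,
        "panel": panel,
        "pheno": pheno,
        "qc_report": qc_report,
        "std_all": std_all,
        "std_auto": std_auto,
        "pca_all": pca_all,
        "pca_auto": pca_auto,
        "sex": sex,
        "truth": truth,
        "kept_mask": keep,
    }


def make_panel(dosages, chroms=None, locations=None, basins=None, alts=None):
    """Small hand-built GenotypePanel from a dosage matrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    chroms = chroms if chroms is not None else ["groupI"] * m
    snps = pd.DataFrame({
        "chrom": chroms,
        "pos": np.arange(1, m + 1) * 100,
        "id": [f"s{j}" for j in range(m)],
        "ref": "A",
        "alt": alts if alts is not None else ["G"] * m,
    })
    samples = pd.DataFrame({
        "id": [f"i{i}" for i in range(n)],
        "location": locations if locations is not None else ["loc01"] * n,
        "basin": basins if basins is not None else ["Maas"] * n,
    })
    return h.GenotypePanel(dosages=dosages, snps=snps, samples=samples)
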