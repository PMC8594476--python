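"""Validation experiments under the generator's study conditions.

Each function runs one end-to-end experiment — planted-truth recovery
through the filter cascade, type-I error of the site-level model under
a null, power of the gene-level rotation test, association-beta
recovery — at a fixed problem size, and returns the measured
quantities.  Both the test suite and the acceptance script call these,
so the numbers reported are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from scredit import association, differential, filtering, metrics
from scredit.config import CellTypeEffect, SimulationConfig
from scredit.differential import PseudobulkTable
from scredit.simulate import simulate_dataset


def _seed32(seed: int, k: int) -> int:
    return (seed * 1000003 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Filter cascade recovery
# ---------------------------------------------------------------------------

def filter_fixture_config(seed: int, n_sites: int = 5000, n_cells: int = 500):
    """The planted-SNP / antisense-decoy / overlap-region fixture."""
    return SimulationConfig(
        n_cells=n_cells,
        n_sites=n_sites,
        n_genes=160,
        snp_fraction=0.05,
        antisense_decoy_fraction=0.05,
        overlap_site_fraction=0.03,
        transcription_rate=0.10,  # enough covered cells at 500-cell scale
        seed=_seed32(seed, 1),
    )


def run_filter_recovery(seed: int, n_sites: int = 5000, n_cells: int = 500):
    """Simulate the fixture, run the cascade, score against truth.

    Returns (dataset, FilterResult, stats dict) where stats holds the
    precision of editing-site recovery and the planted-SNP removal
    fraction among sites that reached the SNP-removal step.
    """
    config = filter_fixture_config(seed, n_sites, n_cells)
    ds = simulate_dataset(config)
    annotation = filtering.GenomeAnnotation(ds.annotation.features)
    result = filtering.run_filter_cascade(
        ds.matrix,
        snps=ds.annotation.snps,
        catalog=ds.annotation.catalog,
        annotation=annotation,
        repeats=ds.annotation.repeats,
        extra_catalogs={"bulk": ds.annotation.bulk_catalog},
    )
    truth = ds.truth.site_table.set_index("site_id")
    kept = result.matrix.sites["site_id"]
    kept_truth = truth.loc[kept]
    n_kept = len(kept)
    precision = (
        float(kept_truth["is_true"].mean()) if n_kept else float("nan")
    )
    # SNP sites that passed the coverage/prevalence step must all have
    # been removed by the SNP filter
    qc_cells = filtering.cell_qc(ds.matrix.cells)
    candidates = filtering.select_candidates(
        ds.matrix.subset_cells(qc_cells["qc_pass"].to_numpy())
    )
    cand_truth = truth.loc[candidates.sites["site_id"]]
    n_snp_candidates = int(cand_truth["is_snp"].sum())
    n_snp_kept = int(kept_truth["is_snp"].sum())
    stats_out = {
        "n_kept": n_kept,
        "precision": precision,
        "n_snp_candidates": n_snp_candidates,
        "n_snp_kept": n_snp_kept,
        "snp_removed_fraction": (
            1.0 - n_snp_kept / n_snp_candidates if n_snp_candidates else 1.0
        ),
    }
    return ds, result, stats_out


# ---------------------------------------------------------------------------
# Site-level model calibration
# ---------------------------------------------------------------------------

def make_null_pseudobulk(
    seed: int,
    n_sites: int = 2000,
    n_regions: int = 2,
    reps_per_cell: int = 2,
    total_mean: float = 800.0,
    total_shape: float = 5.0,
    sample_sd: float = 0.2,
    planted: dict | None = None,
) -> PseudobulkTable:
    """Pseudobulk paired counts with no phenotype effect by default.

    Eight samples arise from 2 phenotypes x ``n_regions`` regions x
    ``reps_per_cell`` subgroup replicates.  Per site, the baseline
    editing proportion is Beta(2, 8); sample proportions wobble around
    it on the logit scale with SD ``sample_sd``; totals are negative
    binomial (a site's summed coverage across ~40 cells of depth ~20).
    ``planted`` may map site index -> logit shift added in inhibitory
    samples to plant a signal.
    """
    rng = np.random.default_rng(_seed32(seed, 2))
    phenos = ["excitatory", "inhibitory"]
    rows = []
    for ph in phenos:
        for r in range(n_regions):
            for k in range(reps_per_cell):
                rows.append(
                    {
                        "sample_id": f"{ph[:2]}{k + 1}|R{r + 1}",
                        "subgroup": f"{ph[:2].capitalize()}{k + 1}",
                        "region": f"R{r + 1}",
                        "phenotype": ph,
                        "n_cells": 40,
                    }
                )
    samples = pd.DataFrame(rows)
    G = len(samples)
    p0 = rng.beta(2.0, 8.0, size=n_sites)
    logit0 = np.log(p0 / (1 - p0))
    eps = rng.normal(0.0, sample_sd, size=(n_sites, G))
    logits = logit0[:, None] + eps
    if planted:
        inh = (samples["phenotype"] == "inhibitory").to_numpy()
        for si, shift in planted.items():
            logits[si, inh] += shift
    p = 1.0 / (1.0 + np.exp(-logits))
    total = rng.negative_binomial(
        total_shape, total_shape / (total_shape + total_mean),
        size=(n_sites, G),
    )
    total = np.maximum(total, 1)
    edited = rng.binomial(total, p)
    sites = pd.DataFrame(
        {
            "site_id": [f"s{i:05d}" for i in range(n_sites)],
            "gene_id": [f"g{i // 4:04d}" for i in range(n_sites)],
        }
    )
    return PseudobulkTable(
        edited=edited, unedited=total - edited, samples=samples, sites=sites
    )


def site_null_type_one_error(
    seed: int, n_sites: int = 2000, alpha: float = 0.05
) -> dict:
    """Empirical type-I error of the site-level NB model on null data."""
    pb = make_null_pseudobulk(seed, n_sites=n_sites)
    res = differential.fit_site_models(pb)
    p = res["p"].dropna().to_numpy()
    return {
        "n_tests": int(len(p)),
        "type_one_error": float((p < alpha).mean()),
        "alpha": alpha,
    }


def gene_null_pvalues(
    seed: int, n_genes: int = 500, sites_per_gene: int = 4, n_perm: int = 2000
) -> np.ndarray:
    """Gene-level rotation p-values under the null."""
    pb = make_null_pseudobulk(seed, n_sites=n_genes * sites_per_gene)
    pb.sites["gene_id"] = [
        f"g{i // sites_per_gene:04d}" for i in range(len(pb.sites))
    ]
    res = differential.gene_directional_test(
        pb, n_perm=n_perm, seed=_seed32(seed, 3)
    )
    return res["p"].to_numpy()


def gene_test_power(
    seed: int,
    n_reps: int = 100,
    n_null_genes: int = 40,
    sites_per_gene: int = 4,
    planted_sites: int = 10,
    logit_shift: float = 0.5,
    depth_mean: float = 20.0,
    cells_per_sample: int = 40,
    n_perm: int = 2000,
    fdr: float = 0.1,
) -> dict:
    """Power to detect one gene with consistently shifted sites.

    Each replicate simulates ``n_null_genes`` null genes plus one gene
    whose ``planted_sites`` sites share a ``logit_shift`` increase in
    inhibitory samples, then checks whether that gene is detected at
    the given FDR by the rotation test.
    """
    detected = 0
    for rep in range(n_reps):
        n_sites = n_null_genes * sites_per_gene + planted_sites
        planted = {
            n_null_genes * sites_per_gene + k: logit_shift
            for k in range(planted_sites)
        }
        pb = make_null_pseudobulk(
            _seed32(seed, 100 + rep),
            n_sites=n_sites,
            total_mean=depth_mean * cells_per_sample,
            planted=planted,
        )
        gene_ids = [
            f"g{i // sites_per_gene:04d}"
            for i in range(n_null_genes * sites_per_gene)
        ] + ["planted"] * planted_sites
        pb.sites["gene_id"] = gene_ids
        res = differential.gene_directional_test(
            pb, n_perm=n_perm, seed=_seed32(seed, 200 + rep)
        )
        row = res[res["gene_id"] == "planted"]
        if len(row) and float(row["fdr"].iloc[0]) < fdr:
            if row["direction"].iloc[0] == "up":  # inhibitory is level 2
                detected += 1
    return {"n_reps": n_reps, "power": detected / n_reps}


# ---------------------------------------------------------------------------
# Association recovery
# ---------------------------------------------------------------------------

def association_config(seed: int, n_cells: int = 2000) -> SimulationConfig:
    return SimulationConfig(
        n_cells=n_cells,
        n_sites=600,
        n_genes=400,  # planted genes must be a tiny share of the TPM total
        assoc_genes=((0, 0.05), (1, -0.05)),
        transcription_rate=0.15,
        celltype_effect=CellTypeEffect(site_fraction=0.0),
        # editing spread maps to abundance spread at 1/beta = 20 decades
        # per editing unit; moderate cell heterogeneity keeps planted
        # genes expressed across the whole range
        cell_effect_sd=0.15,
        seed=_seed32(seed, 4),
    )


def run_association_recovery(seed: int, n_cells: int = 2000) -> dict:
    """Planted-beta recovery, downsampling stability and permutation
    null for the abundance-editing association model."""
    config = association_config(seed, n_cells)
    ds = simulate_dataset(config)
    # the editing index is computed over filtered candidate sites, as in
    # the pipeline: planted SNP sites would otherwise dilute the signal
    mat, _n_removed = filtering.remove_common_snps(
        ds.matrix, ds.annotation.snps
    )
    summaries = metrics.per_cell_indices(mat, "GEI")
    cells = ds.truth.cell_table
    res = association.fit_gene_associations(
        summaries, ds.tpm, cells, min_cells_expr=300
    )
    planted = {f"gene{g:04d}": b for g, b in config.assoc_genes}
    rows = {}
    for gid, beta_true in planted.items():
        row = res[res["gene_id"] == gid].iloc[0]
        rows[gid] = {
            "beta_true": beta_true,
            "beta_hat": float(row["beta"]),
            "se": float(row["se"]),
            "within_2se": bool(abs(row["beta"] - beta_true) <= 2 * row["se"]),
            "significant": bool(row["significant"]),
        }
    ds_res = association.downsample_check(
        res, summaries, ds.tpm, cells, cap=1500, seed=_seed32(seed, 5)
    )
    ds_sig = {
        gid: bool(ds_res[ds_res["gene_id"] == gid]["significant_ds"].iloc[0])
        for gid in planted
    }
    # permutation null: shuffle the editing index across cells
    rng = np.random.default_rng(_seed32(seed, 6))
    perm = summaries.copy()
    perm["GEI"] = rng.permutation(perm["GEI"].to_numpy())
    null_res = association.fit_gene_associations(
        perm, ds.tpm, cells, min_cells_expr=300
    )
    null_p = null_res["p"].dropna().to_numpy()
    return {
        "planted": rows,
        "downsampled_significant": ds_sig,
        "null_raw_rate_05": float((null_p < 0.05).mean()),
        "n_null_tests": int(len(null_p)),
        "n_significant_null": int(null_res["significant"].sum()),
    }


# ---------------------------------------------------------------------------
# Simulator shape checks
# ---------------------------------------------------------------------------

def count_kde_modes(
    values: np.ndarray, grid: int = 512, min_height: float = 0.05
) -> int:
    """Modes of a Gaussian KDE over [0, 1]: local maxima taller than
    ``min_height`` of the global maximum."""
    kde = stats.gaussian_kde(values)
    xs = np.linspace(0.0, 1.0, grid)
    ys = kde(xs)
    peaks = (ys[1:-1] > ys[:-2]) & (ys[1:-1] >= ys[2:])
    tall = ys[1:-1] > min_height * ys.max()
    n = int((peaks & tall).sum())
    # boundary modes
    if ys[0] > ys[1] and ys[0] > min_height * ys.max():
        n += 1
    if ys[-1] > ys[-2] and ys[-1] > min_height * ys.max():
        n += 1
    return n


def simulator_shape(seed: int, n_draws: int = 100000) -> dict:
    """Bimodality of per-cell edited fractions and skewness of
    cross-cell site means under the default configuration."""
    config = SimulationConfig(
        n_cells=800, n_sites=2000, n_genes=80,
        transcription_rate=0.10, seed=_seed32(seed, 7),
    )
    ds = simulate_dataset(config)
    true_sites = ds.truth.site_table["is_true"].to_numpy()
    mat = ds.matrix.subset_sites(true_sites)
    fracs = metrics.per_site_cell_fractions(mat)
    if len(fracs) > n_draws:
        rng = np.random.default_rng(_seed32(seed, 8))
        fracs = rng.choice(fracs, size=n_draws, replace=False)
    summaries = metrics.per_site_summaries(mat)
    means = summaries["mean_maf"].dropna().to_numpy()
    return {
        "n_fraction_draws": int(len(fracs)),
        "n_modes": count_kde_modes(fracs),
        "mean_skewness": float(stats.skew(means)),
    }
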