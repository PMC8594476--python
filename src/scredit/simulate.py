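"""Synthetic single-nucleus RNA editing data with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a toy genome with genes on both strands (some overlapping in
antisense), Alu repeats clustered in introns and 3'UTRs, editing sites
whose per-cell edited-allele frequencies follow a two-point bimodal
mixture with positively skewed cross-cell means, zero-inflated
negative-binomial read depth, genomic-SNP contamination, a planted
phenotype effect on editing, and genes whose abundance is correlated
with per-cell editing with a chosen slope.

Coordinates: gene/feature tables are 1-based inclusive (GFF3 dialect);
repeat intervals are 0-based half-open (BED dialect).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from scredit import io as sio
from scredit.config import ConfigError, SimulationConfig
from scredit.matrix import EditingMatrix

_U5_LEN = 300
_U3_LEN = 1200
_STOP_LEN = 3
_N_CODING_EXONS = 4
_CODING_EXON_LEN = 600
_ALU_LEN = 300
_REPNA_LEN = 200
_FIXED_GENE_BP = (
    _U5_LEN + _N_CODING_EXONS * _CODING_EXON_LEN + _STOP_LEN + _U3_LEN
)
_ANTISENSE_GENE_RATE = 0.12
_W_CONCENTRATION = 3.0


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Annotation + site truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Annotation:
    """Toy genome annotation plus placed editing-site truth."""

    genes: pd.DataFrame
    features: pd.DataFrame  # GFF3 rows (1-based inclusive)
    repeats: pd.DataFrame  # BED convention (0-based half-open)
    sites: pd.DataFrame  # per-site truth
    catalog: pd.DataFrame
    bulk_catalog: pd.DataFrame
    snps: pd.DataFrame
    overlap_regions: pd.DataFrame  # 1-based inclusive


def _build_genes(config: SimulationConfig, rng) -> pd.DataFrame:
    chrom = "chrS1"
    rows = []
    cursor = 1001
    prev = None
    for i in range(config.n_genes):
        length = int(rng.integers(12000, 24001))
        strand = "+" if rng.random() < 0.5 else "-"
        if prev is not None and rng.random() < _ANTISENSE_GENE_RATE:
            # antisense partner overlapping the previous gene's tail
            start = prev["start"] + (prev["end"] - prev["start"]) // 2
            strand = "-" if prev["strand"] == "+" else "+"
        else:
            start = cursor
        end = start + length - 1
        row = {
            "gene_id": f"gene{i:04d}",
            "chrom": chrom,
            "start": int(start),
            "end": int(end),
            "strand": strand,
        }
        rows.append(row)
        cursor = max(cursor, end) + int(rng.integers(2000, 5001))
        prev = row
    return pd.DataFrame(rows)


def _gene_blocks(start: int, end: int, strand: str) -> dict:
    """Feature blocks of one gene, 1-based inclusive.

    Computed in plus orientation then mirrored for minus-strand genes,
    so the 5'UTR of a minus-strand gene sits at the genomic end.
    """
    length = end - start + 1
    intron_total = length - _FIXED_GENE_BP
    n_intr = _N_CODING_EXONS - 1
    intr = intron_total // n_intr
    blocks: dict[str, list] = {
        "five_prime_UTR": [],
        "three_prime_UTR": [],
        "stop_codon": [],
        "exon": [],
        "intron": [],
    }
    pos = start
    blocks["five_prime_UTR"].append((pos, pos + _U5_LEN - 1))
    exon1_start = pos
    pos += _U5_LEN
    coding_starts = []
    for k in range(_N_CODING_EXONS):
        coding_starts.append(pos)
        pos += _CODING_EXON_LEN
        if k < n_intr:
            gap = intr if k < n_intr - 1 else intron_total - intr * (n_intr - 1)
            blocks["intron"].append((pos, pos + gap - 1))
            pos += gap
    blocks["stop_codon"].append((pos, pos + _STOP_LEN - 1))
    pos += _STOP_LEN
    blocks["three_prime_UTR"].append((pos, pos + _U3_LEN - 1))
    # exons: UTRs fused to terminal coding exons, as in real annotation
    blocks["exon"].append((exon1_start, coding_starts[0] + _CODING_EXON_LEN - 1))
    for cs in coding_starts[1:-1]:
        blocks["exon"].append((cs, cs + _CODING_EXON_LEN - 1))
    blocks["exon"].append((coding_starts[-1], end))
    if strand == "-":
        mirror = lambda ab: (start + end - ab[1], start + end - ab[0])  # noqa: E731
        out = {k: sorted(mirror(b) for b in v) for k, v in blocks.items()}
        out["five_prime_UTR"], out["three_prime_UTR"] = (
            out["three_prime_UTR"],
            out["five_prime_UTR"],
        )
        return out
    return blocks


def _features_frame(genes: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    rows = []
    blocks_by_gene = {}
    for g in genes.itertuples():
        blocks = _gene_blocks(g.start, g.end, g.strand)
        blocks_by_gene[g.gene_id] = blocks
        rows.append(
            (g.chrom, "sim", "gene", g.start, g.end, ".", g.strand, ".",
             f"ID={g.gene_id}")
        )
        for ftype in ("exon", "five_prime_UTR", "three_prime_UTR",
                      "stop_codon"):
            for j, (a, b) in enumerate(blocks[ftype]):
                rows.append(
                    (g.chrom, "sim", ftype, a, b, ".", g.strand, ".",
                     f"ID={g.gene_id}.{ftype}.{j};Parent={g.gene_id}")
                )
    df = pd.DataFrame(rows, columns=sio.GFF3_COLUMNS)
    return df, blocks_by_gene


def _place_repeats(genes, blocks_by_gene, config, rng) -> pd.DataFrame:
    """Alu and repetitive non-Alu intervals inside introns/3'UTRs (BED)."""
    rows = []
    for g in genes.itertuples():
        blocks = blocks_by_gene[g.gene_id]
        for a, b in blocks["intron"]:
            if config.alu_fraction > 0:
                for _ in range(int(rng.poisson(1.2))):
                    if b - a < _ALU_LEN + 10:
                        continue
                    s0 = int(rng.integers(a - 1, b - _ALU_LEN))
                    rows.append((g.chrom, s0, s0 + _ALU_LEN, "Alu", 0,
                                 rng.choice(["+", "-"])))
            if rng.random() < 0.5 and b - a > _REPNA_LEN + 10:
                s0 = int(rng.integers(a - 1, b - _REPNA_LEN))
                rows.append((g.chrom, s0, s0 + _REPNA_LEN, "repNonAlu", 0,
                             rng.choice(["+", "-"])))
        if config.alu_fraction > 0 and rng.random() < 0.4:
            a, b = blocks["three_prime_UTR"][0]
            if b - a > _ALU_LEN + 10:
                s0 = int(rng.integers(a - 1, b - _ALU_LEN))
                rows.append((g.chrom, s0, s0 + _ALU_LEN, "Alu", 0,
                             rng.choice(["+", "-"])))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def _overlap_regions(genes: pd.DataFrame) -> pd.DataFrame:
    """Pairwise gene-footprint intersections (any strands), 1-based."""
    rows = []
    g = genes.sort_values("start").reset_index(drop=True)
    for i in range(len(g)):
        for j in range(i + 1, len(g)):
            if g.loc[j, "start"] > g.loc[i, "end"]:
                break
            a = max(g.loc[i, "start"], g.loc[j, "start"])
            b = min(g.loc[i, "end"], g.loc[j, "end"])
            if a <= b:
                rows.append((g.loc[i, "chrom"], a, b))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(a <= pos <= b for a, b in intervals)


def simulate_annotation(config: SimulationConfig) -> Annotation:
    """Generate the toy genome, repeats, editing catalog and SNP list,
    and place the editing-site truth table inside them."""
    config.validate()
    rng = config.rng("annotation")
    genes = _build_genes(config, rng)
    features, blocks_by_gene = _features_frame(genes)
    repeats = _place_repeats(genes, blocks_by_gene, config, rng)
    ovl = _overlap_regions(genes)
    ovl_iv = list(zip(ovl["start"], ovl["end"])) if len(ovl) else []

    alu_iv = repeats[repeats["name"] == "Alu"]
    repna_iv = repeats[repeats["name"] == "repNonAlu"]
    gene_lookup = genes.set_index("gene_id")

    n_sites = config.n_sites
    n_overlap = int(round(config.overlap_site_fraction * n_sites))
    if not len(ovl):
        n_overlap = 0
    n_alu = int(round(config.alu_fraction * n_sites))
    n_repna = int(round(config.rep_nonalu_fraction * n_sites))
    n_nonrep = max(0, n_sites - n_alu - n_repna - n_overlap)

    taken: set[int] = set()
    chrom = "chrS1"

    def _sample_in_interval(table, zero_based=True):
        """Pick a repeat interval, then a free position inside it."""
        for _ in range(10000):
            k = int(rng.integers(0, len(table)))
            row = table.iloc[k]
            lo = row["start"] + 1 if zero_based else row["start"]
            hi = row["end"] if zero_based else row["end"]
            pos = int(rng.integers(lo, hi + 1))
            if pos in taken or _in_any(pos, ovl_iv):
                continue
            return pos
        raise ConfigError("repeat intervals saturated; raise n_genes")

    def _host_gene(pos: int):
        hit = genes[(genes["start"] <= pos) & (genes["end"] >= pos)]
        if len(hit) == 0:
            return None
        return hit.iloc[0]

    recs = []

    def _add(pos, context, in_overlap=False):
        host = _host_gene(pos)
        if host is None:
            return False
        taken.add(pos)
        recs.append(
            {
                "chrom": chrom,
                "pos": pos,
                "gene_id": host["gene_id"],
                "gene_strand": host["strand"],
                "context": context,
                "in_overlap": in_overlap,
            }
        )
        return True

    placed = 0
    guard = 0
    while placed < n_alu and len(alu_iv):
        guard += 1
        if guard > 200 * max(1, n_alu):
            raise ConfigError("could not place Alu sites; too few repeats")
        if _add(_sample_in_interval(alu_iv), "Alu"):
            placed += 1
    placed = 0
    guard = 0
    while placed < n_repna and len(repna_iv):
        guard += 1
        if guard > 200 * max(1, n_repna):
            raise ConfigError(
                "could not place repetitive non-Alu sites; too few repeats"
            )
        if _add(_sample_in_interval(repna_iv), "repNonAlu"):
            placed += 1
    rep_iv = list(
        zip(repeats["start"] + 1, repeats["end"])
    )  # 1-based inclusive
    placed_nonrep = 0
    while placed_nonrep < n_nonrep:
        gi = int(rng.integers(0, len(genes)))
        g = genes.iloc[gi]
        pos = int(rng.integers(g["start"], g["end"] + 1))
        if pos in taken or _in_any(pos, rep_iv) or _in_any(pos, ovl_iv):
            continue
        if _add(pos, "nonrepetitive"):
            placed_nonrep += 1
    # sites inside antisense-overlap regions: catalog rescue exercise
    placed_ovl = 0
    guard = 0
    while placed_ovl < n_overlap:
        guard += 1
        if guard > 50 * max(1, n_overlap):
            break
        k = int(rng.integers(0, len(ovl)))
        a, b = int(ovl.iloc[k]["start"]), int(ovl.iloc[k]["end"])
        pos = int(rng.integers(a, b + 1))
        if pos in taken or _in_any(pos, rep_iv):
            continue
        if _add(pos, "nonrepetitive", in_overlap=True):
            placed_ovl += 1

    sites = pd.DataFrame(recs).sort_values("pos").reset_index(drop=True)
    m = len(sites)
    sites["site_id"] = [f"site{i:05d}" for i in range(m)]

    # variant class observed in unstranded data: cognate with gene strand
    plus = sites["gene_strand"] == "+"
    sites["ref"] = np.where(plus, "A", "T")
    sites["alt"] = np.where(plus, "G", "C")

    # antisense decoys: non-cognate variant class, never cataloged
    eligible = ~sites["in_overlap"].to_numpy()
    n_decoy = int(round(config.antisense_decoy_fraction * m))
    decoy_idx = rng.choice(
        np.flatnonzero(eligible), size=min(n_decoy, eligible.sum()),
        replace=False,
    )
    is_decoy = np.zeros(m, dtype=bool)
    is_decoy[decoy_idx] = True
    sites["is_antisense_decoy"] = is_decoy
    flip = is_decoy & plus.to_numpy()
    sites.loc[flip, ["ref", "alt"]] = ["T", "C"]
    flop = is_decoy & ~plus.to_numpy()
    sites.loc[flop, ["ref", "alt"]] = ["A", "G"]

    # genomic SNPs of the donor (edited fraction ~ dosage/2 everywhere)
    snp_pool = np.flatnonzero(eligible & ~is_decoy)
    n_snp = min(int(round(config.snp_fraction * m)), len(snp_pool))
    snp_idx = rng.choice(snp_pool, size=n_snp, replace=False)
    is_snp = np.zeros(m, dtype=bool)
    is_snp[snp_idx] = True
    sites["is_snp"] = is_snp
    sites["snp_dosage"] = 0
    sites.loc[is_snp, "snp_dosage"] = rng.choice([1, 2], size=n_snp)

    sites["is_true"] = ~(is_snp | is_decoy)

    # catalog membership among true sites only; SNP list stays disjoint
    true_idx = np.flatnonzero(sites["is_true"].to_numpy())
    n_cat = int(round(config.catalog_fraction * len(true_idx)))
    cat_idx = rng.choice(true_idx, size=n_cat, replace=False)
    in_cat = np.zeros(m, dtype=bool)
    in_cat[cat_idx] = True
    sites["in_catalog"] = in_cat
    n_bulk = int(round(config.bulk_fraction * len(true_idx)))
    bulk_idx = rng.choice(true_idx, size=n_bulk, replace=False)
    in_bulk = np.zeros(m, dtype=bool)
    in_bulk[bulk_idx] = True
    sites["in_bulk"] = in_bulk

    # per-site high-mode weight: Beta around the configured mixture weight
    low, high, w_mean = config.bimodal_mix
    if 0 < w_mean < 1:
        w = rng.beta(
            w_mean * _W_CONCENTRATION, (1 - w_mean) * _W_CONCENTRATION, size=m
        )
    else:
        w = np.full(m, float(w_mean))
    sites["w_site"] = w

    # planted phenotype effect on a subset of true sites
    eff = config.celltype_effect
    n_aff = int(round(eff.site_fraction * len(true_idx)))
    aff_idx = rng.choice(true_idx, size=n_aff, replace=False)
    affected = np.zeros(m, dtype=bool)
    affected[aff_idx] = True
    sites["celltype_affected"] = affected

    catalog = sites.loc[
        in_cat, ["chrom", "pos", "gene_strand", "context"]
    ].rename(columns={"gene_strand": "strand"}).reset_index(drop=True)
    bulk_catalog = sites.loc[
        in_bulk, ["chrom", "pos", "gene_strand", "context"]
    ].rename(columns={"gene_strand": "strand"}).reset_index(drop=True)

    snps = sites.loc[is_snp, ["chrom", "pos", "ref", "alt"]].copy()
    # background SNPs away from any site, disjoint from the catalog
    n_extra = max(50, m // 10)
    extra = []
    genome_end = int(genes["end"].max()) + 1000
    while len(extra) < n_extra:
        pos = int(rng.integers(1, genome_end))
        if pos in taken:
            continue
        ref, alt = ("A", "G") if rng.random() < 0.5 else ("T", "C")
        extra.append((chrom, pos, ref, alt))
        taken.add(pos)
    snps = pd.concat(
        [snps, pd.DataFrame(extra, columns=["chrom", "pos", "ref", "alt"])],
        ignore_index=True,
    ).sort_values("pos").reset_index(drop=True)
    _ = gene_lookup  # retained for callers needing gene coordinates

    return Annotation(
        genes=genes,
        features=features,
        repeats=repeats,
        sites=sites,
        catalog=catalog,
        bulk_catalog=bulk_catalog,
        snps=snps,
        overlap_regions=ovl,
    )


# ---------------------------------------------------------------------------
# Cells
# ---------------------------------------------------------------------------

def simulate_cells(config: SimulationConfig) -> pd.DataFrame:
    """Cell metadata: phenotype, subgroup, region, library size, mito
    fraction, complexity, latent editing propensity.

    Exactly ``ceil(high_mito_fraction * n_cells)`` cells get a
    mitochondrial fraction strictly above 0.15, and an equally sized,
    disjoint set gets a low detected-gene count, so QC behaviour is
    forced by construction.
    """
    config.validate()
    rng = config.rng("cells")
    n = config.n_cells
    phenos = list(config.phenotype_proportions)
    probs = np.array([config.phenotype_proportions[p] for p in phenos])
    phenotype = rng.choice(phenos, size=n, p=probs)
    prefix = {p: p[:2].capitalize() for p in phenos}
    sub_k = rng.integers(1, config.n_subgroups_per_phenotype + 1, size=n)
    subgroup = [f"{prefix[p]}{k}" for p, k in zip(phenotype, sub_k)]
    region = rng.choice(list(config.region_labels), size=n)
    library_size = np.round(rng.lognormal(mean=13.8, sigma=0.35, size=n))
    complexity = np.maximum(
        1200, rng.normal(4000, 450, size=n).round()
    ).astype(int)
    mito = np.minimum(rng.beta(2.0, 40.0, size=n), 0.149)

    n_hi = int(np.ceil(config.high_mito_fraction * n))
    n_lo = int(np.ceil(config.low_complexity_fraction * n))
    flagged = rng.choice(n, size=min(n, n_hi + n_lo), replace=False)
    hi_idx, lo_idx = flagged[:n_hi], flagged[n_hi:n_hi + n_lo]
    mito[hi_idx] = 0.151 + 0.2 * rng.random(len(hi_idx))
    complexity[lo_idx] = rng.integers(100, 800, size=len(lo_idx))

    cell_effect = rng.normal(0.0, config.cell_effect_sd, size=n)
    return pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(n)],
            "phenotype": phenotype,
            "subgroup": subgroup,
            "region": region,
            "library_size": library_size.astype(int),
            "mito_fraction": mito,
            "complexity": complexity,
            "cell_effect": cell_effect,
        }
    )


# ---------------------------------------------------------------------------
# Truth + allele counts
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth tables: per-site, per-cell and per-gene parameters."""

    site_table: pd.DataFrame
    cell_table: pd.DataFrame
    gene_table: pd.DataFrame
    config: SimulationConfig


def _site_cell_logits(sites, cells, config):
    """Logit-scale high-mode weight per (site, cell)."""
    eff = config.celltype_effect
    w = _logit(sites["w_site"].to_numpy())[:, None]
    w = w + cells["cell_effect"].to_numpy()[None, :]
    aff = sites["celltype_affected"].to_numpy()[:, None]
    in_ph = (cells["phenotype"] == eff.phenotype).to_numpy()[None, :]
    w = w + eff.log_odds * (aff & in_ph)
    if "assoc_logit_shift" in cells.columns:
        w = w + cells["assoc_logit_shift"].to_numpy()[None, :]
    return w


def _refresh_truth(truth: "SyntheticTruth") -> None:
    """Recompute per-site per-phenotype probabilities and per-cell true
    mean editing from the current logit structure."""
    config = truth.config
    sites, cells = truth.site_table, truth.cell_table
    low, high, _ = config.bimodal_mix
    p = low + (high - low) * _sigmoid(_site_cell_logits(sites, cells, config))
    is_snp = sites["is_snp"].to_numpy()
    p[is_snp] = (sites.loc[is_snp, "snp_dosage"].to_numpy() / 2.0)[:, None]
    for ph in config.phenotype_proportions:
        mask = (cells["phenotype"] == ph).to_numpy()
        sites[f"true_p_{ph}"] = (
            p[:, mask].mean(axis=1) if mask.any() else np.nan
        )
    cells["true_editing"] = p[~is_snp].mean(axis=0)


def build_truth(
    annotation: Annotation, cells: pd.DataFrame, config: SimulationConfig
) -> SyntheticTruth:
    """Assemble the ground-truth tables, including each site's true
    per-phenotype editing probability and each cell's true mean editing
    level (the quantity per-cell editing indices estimate).

    When association genes are planted, :func:`simulate_expression`
    must run before :func:`simulate_allele_counts` so the cells'
    abundance-driven editing shifts are in place;
    :func:`simulate_dataset` handles the ordering.
    """
    sites = annotation.sites.copy()
    rngg = config.rng("genes")
    planted = dict(config.assoc_genes)
    gene_ids = [f"gene{i:04d}" for i in range(config.n_genes)]
    gene_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "planted_beta": [planted.get(i, 0.0) for i in range(config.n_genes)],
            "log10_mean_expr": rngg.normal(1.0, 0.6, size=config.n_genes),
            "length": rngg.integers(500, 5001, size=config.n_genes),
            "expr_rate": rngg.uniform(0.3, 1.0, size=config.n_genes),
            "nb_shape": np.full(config.n_genes, float(config.expr_nb_shape)),
            "abundance_sd": np.full(config.n_genes, 0.3),
        }
    )
    # planted genes mimic abundant, variable, tightly measured
    # transcripts (snoRNA-marker-like): high per-cell biological
    # abundance variation carries the planted association, while
    # high-mean/low-dispersion counts and a long gene body keep
    # measurement noise and TPM self-normalization negligible
    planted_mask = gene_table["planted_beta"] != 0
    gene_table.loc[planted_mask, "expr_rate"] = 1.0
    gene_table.loc[planted_mask, "log10_mean_expr"] = 1.0
    gene_table.loc[planted_mask, "nb_shape"] = 200.0
    gene_table.loc[planted_mask, "length"] = 5000
    gene_table.loc[planted_mask, "abundance_sd"] = 0.7
    cell_table = cells.copy()
    cell_table["assoc_logit_shift"] = 0.0
    truth = SyntheticTruth(sites, cell_table, gene_table, config)
    _refresh_truth(truth)
    return truth


def simulate_allele_counts(
    truth: SyntheticTruth, config: SimulationConfig
) -> EditingMatrix:
    """Draw depths and edited-allele counts for every (site, cell).

    Depth is zero-inflated negative binomial: a site is transcribed in a
    cell with probability ``transcription_rate``; transcribed entries
    get depth >= 1.  The edited count is binomial with a per-cell,
    per-site probability from the two-point mixture (giving the bimodal
    per-cell edited-fraction distribution), except at SNP sites where
    the alternate fraction tracks allele dosage/2 in every cell.
    """
    rng = config.rng("counts")
    sites, cells = truth.site_table, truth.cell_table
    S, C = len(sites), len(cells)
    mean, shape = config.coverage_nb
    transcribed = rng.random((S, C)) < config.transcription_rate
    nb_p = shape / (shape + mean)
    depth = np.where(
        transcribed,
        np.maximum(1, rng.negative_binomial(shape, nb_p, size=(S, C))),
        0,
    ).astype(np.int32)

    low, high, _ = config.bimodal_mix
    w_eff = _sigmoid(_site_cell_logits(sites, cells, config))
    high_mode = rng.random((S, C)) < w_eff
    p = np.where(high_mode, high, low)
    is_snp = sites["is_snp"].to_numpy()
    p[is_snp] = (sites.loc[is_snp, "snp_dosage"].to_numpy() / 2.0)[:, None]
    alt = rng.binomial(depth, p).astype(np.int32)

    depth_sp = sp.csr_matrix(depth)
    alt_sp = depth_sp.copy()
    alt_sp.data = alt[depth > 0]  # row-major order matches CSR layout
    site_cols = [
        "site_id", "chrom", "pos", "ref", "alt", "gene_id", "gene_strand",
        "context", "in_catalog", "in_bulk", "is_snp", "is_antisense_decoy",
        "in_overlap", "is_true",
    ]
    return EditingMatrix(
        sites[site_cols].copy(), cells.copy(), alt_sp, depth_sp
    )


def _solve_assoc_shifts(
    truth: SyntheticTruth, target_delta: np.ndarray
) -> np.ndarray:
    """Per-cell logit offsets realizing exact mean-editing shifts.

    Solves, for each cell j, mean_s sigmoid(L_sj + shift_j) =
    base_j + target_delta_j / (high - low) over non-SNP sites by
    Newton iteration (the map is smooth and strictly increasing).
    """
    config = truth.config
    low, high, _ = config.bimodal_mix
    span = high - low
    sites, cells = truth.site_table, truth.cell_table
    keep = ~sites["is_snp"].to_numpy()
    base_cells = cells.drop(columns=["assoc_logit_shift"])
    L = _site_cell_logits(sites[keep], base_cells, config)
    base = _sigmoid(L).mean(axis=0)
    target = np.clip(base + target_delta / span, 1e-4, 1 - 1e-4)
    shift = np.zeros(L.shape[1])
    for _ in range(50):
        s = _sigmoid(L + shift[None, :])
        f = s.mean(axis=0) - target
        fprime = np.maximum((s * (1 - s)).mean(axis=0), 1e-8)
        step = f / fprime
        shift -= step
        if np.max(np.abs(f)) < 1e-12:
            break
    return shift


def simulate_expression(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-by-cell counts and TPM.

    Each gene's per-cell log10 abundance varies biologically around its
    mean (``abundance_sd`` decades); counts are negative binomial on
    top.  For planted association genes, each cell's editing propensity
    is then shifted by beta x (observed log10 TPM - mean), i.e.
    abundance acts as an editing modulator, so the per-cell editing
    index regresses on log10 TPM with slope beta by construction.
    Updates ``truth.cell_table`` (assoc_logit_shift, true_editing) as a
    side effect when associations are planted.
    """
    rng = config.rng("expression")
    gt, ct = truth.gene_table, truth.cell_table
    G, C = len(gt), len(ct)
    log10_mu = (
        gt["log10_mean_expr"].to_numpy()[:, None]
        + rng.normal(0.0, 1.0, size=(G, C))
        * gt["abundance_sd"].to_numpy()[:, None]
    )
    lib = rng.lognormal(0.0, 0.1, size=C)
    lam = (10.0 ** log10_mu) * lib[None, :]
    shape = gt["nb_shape"].to_numpy()[:, None]
    counts = rng.negative_binomial(
        shape, shape / (shape + lam)
    ).astype(np.int64)
    expressed = rng.random((G, C)) < gt["expr_rate"].to_numpy()[:, None]
    counts = np.where(expressed, counts, 0)

    lengths = gt["length"].to_numpy()[:, None].astype(float)
    rate = counts / lengths
    col = rate.sum(axis=0)
    col[col == 0] = 1.0
    tpm = rate / col[None, :] * 1e6

    beta = gt["planted_beta"].to_numpy()
    planted = np.flatnonzero(beta != 0)
    if len(planted):
        delta = np.zeros(C)
        for gi in planted:
            x = tpm[gi]
            pos = x > 0
            if pos.sum() < 2:
                continue
            lx = np.where(pos, np.log10(np.where(pos, x, 1.0)), 0.0)
            mean_lx = lx[pos].mean()
            delta += np.where(pos, beta[gi] * (lx - mean_lx), 0.0)
        ct["assoc_logit_shift"] = _solve_assoc_shifts(truth, delta)
        _refresh_truth(truth)

    cols = ct["cell_id"].to_numpy()
    idx = gt["gene_id"].to_numpy()
    return (
        pd.DataFrame(counts, index=idx, columns=cols),
        pd.DataFrame(tpm, index=idx, columns=cols),
    )


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticDataset:
    """Everything one simulation run produces."""

    config: SimulationConfig
    annotation: Annotation
    truth: SyntheticTruth
    matrix: EditingMatrix
    counts: pd.DataFrame
    tpm: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run every sub-generator off the master seed."""
    config.validate()
    annotation = simulate_annotation(config)
    cells = simulate_cells(config)
    truth = build_truth(annotation, cells, config)
    # expression first: planted abundance-editing shifts feed the counts
    counts, tpm = simulate_expression(truth, config)
    matrix = simulate_allele_counts(truth, config)
    return SyntheticDataset(config, annotation, truth, matrix, counts, tpm)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write the complete fixture set as plain-text standard formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.write_gff3(outdir / "genes.gff3", ds.annotation.features)
    sio.write_bed(outdir / "repeats.bed", ds.annotation.repeats)
    sio.write_tsv(outdir / "catalog.tsv", ds.annotation.catalog)
    sio.write_tsv(outdir / "bulk_sites.tsv", ds.annotation.bulk_catalog)
    sio.write_tsv(outdir / "snps.tsv", ds.annotation.snps)
    sio.write_tsv(outdir / "cells.tsv", ds.truth.cell_table)
    sio.write_tsv(outdir / "truth_sites.tsv", ds.truth.site_table)
    sio.write_tsv(outdir / "truth_genes.tsv", ds.truth.gene_table)
    ds.matrix.to_dir(outdir / "matrix")
    ds.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    ds.tpm.to_csv(outdir / "tpm.tsv", sep="\t", index_label="gene_id")
    sio.write_vcf(
        outdir / "variants.vcf",
        ds.matrix.sites,
        ds.matrix.alt.toarray(),
        ds.matrix.depth.toarray(),
        ds.matrix.cells["cell_id"],
    )
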