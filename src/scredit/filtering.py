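"""Editing-site detection and filtering from per-cell variant calls.

The cascade enriches unstranded single-nucleus variant calls for true
A-to-I editing sites:

1. cell QC (mitochondrial fraction, library complexity);
2. candidate selection: A>G / T>C sites covered by >= 5 reads with a
   minor-allele count >= 2 in at least 10 passing cells;
3. removal of common genomic SNPs (exact chrom/pos/ref/alt match);
4. strand filter: keep a site iff it is cataloged, or lies inside
   exactly one gene's footprint with the cognate variant class (A>G on
   plus-strand genes, T>C on minus-strand genes);
5. annotation of repeat context (Alu > repetitive non-Alu >
   nonrepetitive), genic feature, and novelty versus the catalog(s).

All steps are pure functions of their inputs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from scredit.io import FormatError
from scredit.matrix import EditingMatrix

MITO_MAX_DEFAULT = 0.15
MIN_COMPLEXITY_DEFAULT = 1000
EDITING_CLASSES = {("A", "G"), ("T", "C")}
FEATURE_PRECEDENCE = [
    "stop_codon",
    "three_prime_UTR",
    "five_prime_UTR",
    "exon",
    "intron",
]
FEATURE_LABEL = {
    "stop_codon": "stop_codon",
    "three_prime_UTR": "3'UTR",
    "five_prime_UTR": "5'UTR",
    "exon": "exon",
    "intron": "intron",
}


# ---------------------------------------------------------------------------
# Cell QC
# ---------------------------------------------------------------------------

def cell_qc(
    cells: pd.DataFrame,
    mito_max: float = MITO_MAX_DEFAULT,
    min_complexity: int = MIN_COMPLEXITY_DEFAULT,
) -> pd.DataFrame:
    """Flag cells failing QC.

    A cell fails iff its mitochondrial read fraction is strictly greater
    than ``mito_max`` ("more than 15%" convention: exactly 0.15 passes)
    or its detected-gene count is strictly below ``min_complexity``.
    Adds ``qc_pass`` and ``qc_reason`` ('' | 'mito' | 'complexity' |
    'mito+complexity') columns.
    """
    out = cells.copy()
    mito_fail = out["mito_fraction"].to_numpy() > mito_max
    cx_fail = out["complexity"].to_numpy() < min_complexity
    out["qc_pass"] = ~(mito_fail | cx_fail)
    reason = np.where(
        mito_fail & cx_fail,
        "mito+complexity",
        np.where(mito_fail, "mito", np.where(cx_fail, "complexity", "")),
    )
    out["qc_reason"] = reason
    return out


def qc_report(cells: pd.DataFrame) -> dict:
    """Counts of QC failures by reason."""
    reason = cells["qc_reason"]
    return {
        "n_cells": len(cells),
        "n_fail": int((~cells["qc_pass"]).sum()),
        "n_fail_mito": int(reason.str.contains("mito").sum()),
        "n_fail_complexity": int(reason.str.contains("complexity").sum()),
    }


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------

def select_candidates(
    matrix: EditingMatrix,
    min_depth: int = 5,
    min_alt: int = 2,
    min_cells: int = 10,
) -> EditingMatrix:
    """Retain A>G / T>C sites qualifying in at least ``min_cells`` cells.

    A cell qualifies a site when depth >= ``min_depth`` and minor-allele
    count >= ``min_alt`` in that cell (each qualifying cell must satisfy
    both thresholds individually).  Adds an ``n_qualifying`` column.
    """
    if min_cells < 1:
        raise ValueError(f"min_cells must be >= 1, got {min_cells}")
    alt_d, depth_d, _idx, indptr = matrix.aligned_data()
    qual = ((depth_d >= min_depth) & (alt_d >= min_alt)).astype(np.int64)
    n_qual = np.add.reduceat(
        np.append(qual, 0), indptr[:-1]
    ) * (np.diff(indptr) > 0)
    classes = list(
        zip(matrix.sites["ref"].astype(str), matrix.sites["alt"].astype(str))
    )
    is_editing_class = np.array([c in EDITING_CLASSES for c in classes])
    keep = is_editing_class & (n_qual >= min_cells)
    out = matrix.subset_sites(keep)
    out.sites["n_qualifying"] = n_qual[keep]
    return out


# ---------------------------------------------------------------------------
# SNP removal
# ---------------------------------------------------------------------------

def remove_common_snps(
    matrix: EditingMatrix, snps: pd.DataFrame
) -> tuple[EditingMatrix, int]:
    """Drop sites exactly matching a common-SNP record on
    (chrom, pos, ref, alt).  Returns (filtered matrix, n removed)."""
    snp_keys = set(
        zip(
            snps["chrom"].astype(str),
            snps["pos"].astype(int),
            snps["ref"].astype(str),
            snps["alt"].astype(str),
        )
    )
    keys = list(
        zip(
            matrix.sites["chrom"].astype(str),
            matrix.sites["pos"].astype(int),
            matrix.sites["ref"].astype(str),
            matrix.sites["alt"].astype(str),
        )
    )
    keep = np.array([k not in snp_keys for k in keys], dtype=bool)
    return matrix.subset_sites(keep), int((~keep).sum())


# ---------------------------------------------------------------------------
# Annotation-backed filters
# ---------------------------------------------------------------------------

class GenomeAnnotation:
    """Interval lookups over a GFF3 gene table (1-based inclusive)."""

    def __init__(self, gff3: pd.DataFrame):
        if "feature_id" not in gff3.columns:
            gff3 = gff3.copy()
            gff3["feature_id"] = gff3["attributes"].map(
                lambda attrs: next(
                    (
                        part.split("=", 1)[1]
                        for part in str(attrs).split(";")
                        if part.startswith(("ID=", "Parent="))
                    ),
                    "",
                )
            )
        if len(gff3) and gff3["strand"].isin([".", "?"]).any():
            bad = gff3[gff3["strand"].isin([".", "?"])].iloc[0]
            raise FormatError(
                f"annotation record {bad['type']} {bad['feature_id']!r} "
                "lacks strand information"
            )
        self.genes = gff3[gff3["type"] == "gene"].reset_index(drop=True)
        self._gene_trees: dict[str, IntervalTree] = {}
        for g in self.genes.itertuples():
            tree = self._gene_trees.setdefault(g.seqid, IntervalTree())
            # half-open internal representation
            tree.addi(g.start, g.end + 1, (g.feature_id, g.strand))
        self._feature_trees: dict[tuple, IntervalTree] = {}
        for f in gff3[gff3["type"] != "gene"].itertuples():
            key = (f.seqid, f.type)
            tree = self._feature_trees.setdefault(key, IntervalTree())
            tree.addi(f.start, f.end + 1, f.feature_id)

    def genes_at(self, chrom: str, pos: int) -> list[tuple[str, str]]:
        """(gene_id, strand) of every gene whose footprint covers pos."""
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree[pos])

    def feature_at(self, chrom: str, pos: int, ftype: str) -> bool:
        tree = self._feature_trees.get((chrom, ftype))
        return tree is not None and bool(tree[pos])


def _catalog_keys(catalog: pd.DataFrame) -> set:
    return set(
        zip(catalog["chrom"].astype(str), catalog["pos"].astype(int))
    )


def strand_filter(
    matrix: EditingMatrix,
    catalog: pd.DataFrame,
    annotation: GenomeAnnotation,
) -> EditingMatrix:
    """Apply the strand/overlap rule with catalog rescue.

    A site is kept iff (i) it is present in the catalog, or (ii) it lies
    inside exactly one gene's footprint (no overlap with any other gene,
    either strand) and its variant class is cognate with that gene's
    strand.  Kept sites get ``gene_strand``, ``gene_id``, a
    ``catalog_rescued`` flag and canonical A>G identity on the gene
    strand (``canonical_ref``/``canonical_alt``).
    """
    cat = _catalog_keys(catalog)
    sites = matrix.sites
    keep = np.zeros(len(sites), dtype=bool)
    gene_ids, strands, rescued = [], [], []
    for i, row in enumerate(sites.itertuples()):
        chrom, pos = str(row.chrom), int(row.pos)
        hits = annotation.genes_at(chrom, pos)
        in_cat = (chrom, pos) in cat
        cognate = None
        if len(hits) == 1:
            gid, strand = hits[0]
            cognate = (row.ref, row.alt) == (
                ("A", "G") if strand == "+" else ("T", "C")
            )
        if in_cat:
            keep[i] = True
            if len(hits) >= 1:
                gid, strand = hits[0]
            else:
                gid, strand = "", "+"
            gene_ids.append(gid)
            strands.append(strand)
            rescued.append(not (len(hits) == 1 and cognate))
        elif len(hits) == 1 and cognate:
            keep[i] = True
            gene_ids.append(hits[0][0])
            strands.append(hits[0][1])
            rescued.append(False)
    out = matrix.subset_sites(keep)
    out.sites["gene_id"] = gene_ids
    out.sites["gene_strand"] = strands
    out.sites["catalog_rescued"] = rescued
    out.sites["canonical_ref"] = "A"
    out.sites["canonical_alt"] = "G"
    return out


def annotate_context(
    sites: pd.DataFrame, repeats: pd.DataFrame
) -> pd.DataFrame:
    """Label each site Alu / repNonAlu / nonrepetitive from a BED6
    repeat table (0-based half-open); Alu takes precedence when
    intervals of both kinds cover a site."""
    trees: dict[tuple, IntervalTree] = {}
    for r in repeats.itertuples():
        label = "Alu" if str(r.name) == "Alu" else "repNonAlu"
        tree = trees.setdefault((str(r.chrom), label), IntervalTree())
        if r.end > r.start:
            tree.addi(r.start, r.end)  # already half-open
    out = sites.copy()
    labels = []
    for row in out.itertuples():
        p0 = int(row.pos) - 1  # BED is 0-based
        chrom = str(row.chrom)
        if (chrom, "Alu") in trees and trees[(chrom, "Alu")][p0]:
            labels.append("Alu")
        elif (chrom, "repNonAlu") in trees and trees[(chrom, "repNonAlu")][p0]:
            labels.append("repNonAlu")
        else:
            labels.append("nonrepetitive")
    out["context"] = labels
    return out


def annotate_feature(
    sites: pd.DataFrame, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Assign the most specific genic feature at each site.

    Precedence stop_codon > 3'/5'UTR > exon > intron; intron means
    inside a gene footprint but outside every exon; sites outside all
    genes get 'other'.
    """
    out = sites.copy()
    feats = []
    for row in out.itertuples():
        chrom, pos = str(row.chrom), int(row.pos)
        label = None
        for ftype in FEATURE_PRECEDENCE[:-1]:
            if annotation.feature_at(chrom, pos, ftype):
                label = FEATURE_LABEL[ftype]
                break
        if label is None:
            label = "intron" if annotation.genes_at(chrom, pos) else "other"
        feats.append(label)
    out["feature"] = feats
    return out


def classify_novelty(
    sites: pd.DataFrame, catalogs: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Mark each site novel iff absent from every catalog; keep one
    boolean membership column per catalog for intersection reporting."""
    if not catalogs:
        raise ValueError("at least one catalog is required")
    out = sites.copy()
    any_member = np.zeros(len(out), dtype=bool)
    site_keys = list(
        zip(out["chrom"].astype(str), out["pos"].astype(int))
    )
    for name, cat in catalogs.items():
        keys = _catalog_keys(cat)
        member = np.array([k in keys for k in site_keys])
        out[f"in_{name}"] = member
        any_member |= member
    out["novel"] = ~any_member
    out["catalog_status"] = np.where(any_member, "cataloged", "novel")
    return out


# ---------------------------------------------------------------------------
# Neighbor distances
# ---------------------------------------------------------------------------

def neighbor_distances(sites: pd.DataFrame) -> pd.DataFrame:
    """Distance from each site to its nearest same-context neighbor on
    the same chromosome.  Singletons in a (chrom, context) class are
    excluded (distance undefined)."""
    rows = []
    for (chrom, context), grp in sites.groupby(["chrom", "context"]):
        pos = np.sort(grp["pos"].to_numpy())
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        left = np.concatenate([[np.iinfo(np.int64).max], gaps])
        right = np.concatenate([gaps, [np.iinfo(np.int64).max]])
        nearest = np.minimum(left, right)
        for p, d in zip(pos, nearest):
            rows.append((chrom, context, int(p), int(d)))
    return pd.DataFrame(
        rows, columns=["chrom", "context", "pos", "nearest_distance"]
    )


def neighbor_distance_medians(distances: pd.DataFrame) -> pd.Series:
    return distances.groupby("context")["nearest_distance"].median()


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FilterResult:
    matrix: EditingMatrix
    log: dict


def run_filter_cascade(
    matrix: EditingMatrix,
    snps: pd.DataFrame,
    catalog: pd.DataFrame,
    annotation: GenomeAnnotation,
    repeats: pd.DataFrame,
    extra_catalogs: dict[str, pd.DataFrame] | None = None,
    min_depth: int = 5,
    min_alt: int = 2,
    min_cells: int = 10,
    mito_max: float = MITO_MAX_DEFAULT,
    min_complexity: int = MIN_COMPLEXITY_DEFAULT,
) -> FilterResult:
    """QC -> candidates -> SNP removal -> strand filter -> annotation.

    The documented order is canonical; SNP removal and the strand filter
    commute because they test disjoint predicates.
    """
    log: dict = {}
    cells = cell_qc(matrix.cells, mito_max, min_complexity)
    log["qc"] = qc_report(cells)
    mat = matrix.subset_cells(cells["qc_pass"].to_numpy())
    mat.cells = cells[cells["qc_pass"]].reset_index(drop=True)
    log["n_input_sites"] = mat.shape[0]
    mat = select_candidates(mat, min_depth, min_alt, min_cells)
    log["n_candidates"] = mat.shape[0]
    mat, n_snp = remove_common_snps(mat, snps)
    log["n_snp_removed"] = n_snp
    mat = strand_filter(mat, catalog, annotation)
    log["n_after_strand"] = mat.shape[0]
    mat.sites = annotate_context(mat.sites, repeats)
    mat.sites = annotate_feature(mat.sites, annotation)
    all_catalogs = {"catalog": catalog}
    if extra_catalogs:
        all_catalogs.update(extra_catalogs)
    mat.sites = classify_novelty(mat.sites, all_catalogs)
    log["n_novel"] = int(mat.sites["novel"].sum())
    return FilterResult(mat, log)
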