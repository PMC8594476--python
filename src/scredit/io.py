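"""Readers and writers for the standard formats the pipeline touches.

Conventions: VCF and GFF3 coordinates are 1-based inclusive, BED is
0-based half-open.  All conversions live here; everything downstream
works with 1-based positions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

GFF3_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def load_variants(vcf_path, cells: pd.DataFrame | None = None) -> pd.DataFrame:
    """Stream per-cell SNV records out of a multi-sample VCF.

    Returns one row per cell x site x alternate allele with columns
    chrom, pos, ref, alt, cell_id, ref_depth, alt_depth.  Multi-allelic
    records are split into biallelic ones; indel alleles are dropped.
    Cells with zero total depth at a site are omitted.

    Raises
    ------
    FormatError
        If the VCF lacks a per-sample allele-depth (AD) field.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if cells is not None:
        keep = set(cells["cell_id"].astype(str))
        sample_mask = np.array([s in keep for s in samples])
    else:
        sample_mask = np.ones(len(samples), dtype=bool)
    rows: dict[str, list] = {
        "chrom": [],
        "pos": [],
        "ref": [],
        "alt": [],
        "cell_id": [],
        "ref_depth": [],
        "alt_depth": [],
    }
    kept_samples = [s for s, m in zip(samples, sample_mask) if m]
    for record in vcf:
        ref = record.REF
        if len(ref) != 1:
            continue  # indel / MNP reference
        ad = record.format("AD")
        if ad is None:
            raise FormatError(
                f"{vcf_path}: record {record.CHROM}:{record.POS} lacks the "
                "AD (allele depth) FORMAT field"
            )
        ad = np.asarray(ad)
        ad = np.where(ad < 0, 0, ad)  # missing encoded negative
        for alt_index, alt in enumerate(record.ALT):
            if len(alt) != 1 or alt == "*":
                continue
            if ad.shape[1] < alt_index + 2:
                continue  # AD collapsed: no sample carries data
            refd = ad[sample_mask, 0]
            altd = ad[sample_mask, alt_index + 1]
            covered = (refd + altd) > 0
            n = int(covered.sum())
            if n == 0:
                continue
            rows["chrom"].extend([record.CHROM] * n)
            rows["pos"].extend([record.POS] * n)
            rows["ref"].extend([ref] * n)
            rows["alt"].extend([alt] * n)
            rows["cell_id"].extend(
                [s for s, c in zip(kept_samples, covered) if c]
            )
            rows["ref_depth"].extend(refd[covered].tolist())
            rows["alt_depth"].extend(altd[covered].tolist())
    return pd.DataFrame(rows)


def write_vcf(
    path,
    sites: pd.DataFrame,
    alt_counts: np.ndarray,
    depths: np.ndarray,
    cell_ids,
) -> None:
    """Write a multi-sample VCF v4.2 with GT:AD:DP per cell.

    ``alt_counts`` and ``depths`` are dense (n_sites, n_cells) arrays;
    cells with zero depth at a site get a missing genotype.
    """
    path = Path(path)
    cell_ids = [str(c) for c in cell_ids]
    header = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Allelic depths for the ref and alt alleles">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for chrom in pd.unique(sites["chrom"]):
        header.append(f"##contig=<ID={chrom}>")
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cell_ids)
    )
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
        for i in order:
            row = sites.iloc[i]
            dp = depths[i]
            ad = alt_counts[i]
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                ".",
                str(row["ref"]),
                str(row["alt"]),
                ".",
                "PASS",
                ".",
                "GT:AD:DP",
            ]
            cells_out = []
            for d, a in zip(dp, ad):
                if d <= 0:
                    cells_out.append("./.:.:.")
                else:
                    gt = "0/1" if 0 < a < d else ("1/1" if a >= d else "0/0")
                    cells_out.append(f"{gt}:{int(d - a)},{int(a)}:{int(d)}")
            fh.write("\t".join(fields + cells_out) + "\n")


def load_snp_list(path) -> pd.DataFrame:
    """Read a common-SNP list (TSV with chrom, pos, ref, alt columns, or
    a VCF) into a normalized DataFrame."""
    path = Path(path)
    if path.suffix in {".vcf", ".gz"} or str(path).endswith(".vcf.gz"):
        from cyvcf2 import VCF

        rows = []
        for rec in VCF(str(path)):
            for alt in rec.ALT:
                if len(rec.REF) == 1 and len(alt) == 1:
                    rows.append((rec.CHROM, rec.POS, rec.REF, alt))
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: SNP list missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

def load_gff3(path) -> pd.DataFrame:
    """Parse a GFF3 file into a DataFrame (1-based inclusive coordinates)
    with an extracted ``ID``/``Parent``-derived ``feature_id`` column."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=GFF3_COLUMNS,
            dtype={"seqid": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: not parseable as GFF3: {exc}") from exc
    if df.empty:
        return df.assign(feature_id=pd.Series(dtype=str))
    bad = df[~df["strand"].isin(["+", "-", ".", "?"])]
    if len(bad):
        line = bad.index[0] + 1
        raise FormatError(f"{path}: line {line}: invalid strand field")
    if not (df["start"] <= df["end"]).all():
        line = int(df.index[df["start"] > df["end"]][0]) + 1
        raise FormatError(f"{path}: line {line}: start > end")

    def _feature_id(attrs: str) -> str:
        for part in str(attrs).split(";"):
            if part.startswith("ID="):
                return part[3:]
        for part in str(attrs).split(";"):
            if part.startswith("Parent="):
                return part[7:]
        return ""

    df["feature_id"] = df["attributes"].map(_feature_id)
    return df


def write_gff3(path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        df[GFF3_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def load_bed(path) -> pd.DataFrame:
    """Read a BED6 file; returns 0-based half-open intervals with a
    ``name`` column (Alu vs repetitive non-Alu labels for repeats)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    return df


def write_bed(path, df: pd.DataFrame) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    out = df.copy()
    for c in cols:
        if c not in out.columns:
            out[c] = "." if c in {"name", "strand"} else 0
    out[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# TSV / MTX helpers
# ---------------------------------------------------------------------------

def load_catalog(path) -> pd.DataFrame:
    """Known-editing-site catalog: TSV with chrom, pos, strand[, context]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: catalog missing columns {sorted(missing)}")
    return df


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_expression(path) -> pd.DataFrame:
    """Gene-by-cell expression table (TSV with gene_id index, or an MTX
    triplet directory written by :func:`write_expression`)."""
    path = Path(path)
    if path.is_dir():
        from scipy.io import mmread

        mat = mmread(str(path / "matrix.mtx")).tocsr()
        genes = pd.read_csv(path / "genes.tsv", sep="\t")["gene_id"]
        cells = pd.read_csv(path / "cells.tsv", sep="\t")["cell_id"]
        return pd.DataFrame(
            mat.toarray(), index=genes.to_numpy(), columns=cells.to_numpy()
        )
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")
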