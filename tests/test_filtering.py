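"""Filter cascade: QC, candidate selection, SNP removal, strand rule,
context/feature annotation, novelty, neighbor distances."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from scredit import filtering
from scredit.filtering import GenomeAnnotation
from scredit.io import FormatError


def _cells_df(mito, complexity):
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(mito))],
            "mito_fraction": mito,
            "complexity": complexity,
        }
    )


class TestCellQc:
    def test_mito_boundary_is_strict(self):
        cells = _cells_df([0.16, 0.15, 0.14], [5000, 5000, 5000])
        out = filtering.cell_qc(cells)
        assert list(out["qc_pass"]) == [False, True, True]
        assert out["qc_reason"].iloc[0] == "mito"

    def test_planted_failures_counted(self):
        rng = np.random.default_rng(0)
        mito = np.full(100, 0.05)
        cx = np.full(100, 5000)
        bad = rng.choice(100, size=7, replace=False)
        mito[bad[:4]] = 0.2
        cx[bad[4:]] = 100
        out = filtering.cell_qc(_cells_df(mito, cx))
        rep = filtering.qc_report(out)
        assert rep["n_fail"] == 7
        assert rep["n_fail_mito"] == 4
        assert rep["n_fail_complexity"] == 3


class TestSelectCandidates:
    def _matrix_with_qualifying(self, n_qual, n_cells=20):
        depth = np.zeros((1, n_cells), dtype=int)
        alt = np.zeros((1, n_cells), dtype=int)
        depth[0, :n_qual] = 5
        alt[0, :n_qual] = 2
        # extra covered-but-unqualified cells
        depth[0, n_qual : n_qual + 3] = 4
        alt[0, n_qual : n_qual + 3] = 1
        return make_matrix(alt, depth)

    def test_prevalence_boundary_inclusive(self):
        kept = filtering.select_candidates(self._matrix_with_qualifying(10))
        assert kept.shape[0] == 1
        assert kept.sites["n_qualifying"].iloc[0] == 10
        dropped = filtering.select_candidates(self._matrix_with_qualifying(9))
        assert dropped.shape[0] == 0

    def test_non_editing_class_never_candidate(self):
        depth = np.full((1, 20), 10)
        alt = np.full((1, 20), 5)
        m = make_matrix(alt, depth)
        m.sites["ref"], m.sites["alt"] = "C", "T"
        assert filtering.select_candidates(m).shape[0] == 0

    def test_min_cells_validation(self):
        with pytest.raises(ValueError, match="min_cells"):
            filtering.select_candidates(
                self._matrix_with_qualifying(10), min_cells=0
            )

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(42)
        depth = rng.integers(0, 12, size=(50, 30))
        alt = rng.binomial(depth, 0.3)
        refs = rng.choice(["A", "T", "C"], size=50)
        alts = np.where(refs == "A", "G", np.where(refs == "T", "C", "T"))
        m = make_matrix(alt, depth)
        m.sites["ref"], m.sites["alt"] = refs, alts
        kept = filtering.select_candidates(
            m, min_depth=5, min_alt=2, min_cells=3
        )
        expected = []
        for i in range(50):
            if (refs[i], alts[i]) not in {("A", "G"), ("T", "C")}:
                continue
            n = sum(
                1
                for j in range(30)
                if depth[i, j] >= 5 and alt[i, j] >= 2
            )
            if n >= 3:
                expected.append(f"s{i}")
        assert list(kept.sites["site_id"]) == expected


class TestSnpRemoval:
    def test_exact_match_removed_variant_mismatch_kept(self):
        depth = np.full((2, 5), 10)
        alt = np.full((2, 5), 3)
        m = make_matrix(alt, depth)
        snps = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [100, 200],
                "ref": ["A", "A"],
                "alt": ["G", "C"],  # second mismatches the site's A>G
            }
        )
        out, n = filtering.remove_common_snps(m, snps)
        assert n == 1
        assert list(out.sites["pos"]) == [200]


def _toy_annotation():
    """Two isolated genes (one per strand) plus an antisense pair."""
    rows = [
        ("chr1", "sim", "gene", 1000, 2000, ".", "+", ".", "ID=gplus"),
        ("chr1", "sim", "gene", 3000, 4000, ".", "-", ".", "ID=gminus"),
        ("chr1", "sim", "gene", 5000, 6000, ".", "+", ".", "ID=gA"),
        ("chr1", "sim", "gene", 5500, 6500, ".", "-", ".", "ID=gB"),
        ("chr1", "sim", "exon", 1000, 1200, ".", "+", ".",
         "ID=gplus.e1;Parent=gplus"),
        ("chr1", "sim", "three_prime_UTR", 1900, 2000, ".", "+", ".",
         "ID=gplus.u3;Parent=gplus"),
    ]
    gff = pd.DataFrame(
        rows,
        columns=["seqid", "source", "type", "start", "end", "score",
                 "strand", "phase", "attributes"],
    )
    return GenomeAnnotation(gff)


class TestStrandFilter:
    def _matrix(self, positions, refs, alts):
        n = len(positions)
        depth = np.full((n, 4), 10)
        alt = np.full((n, 4), 3)
        m = make_matrix(alt, depth)
        m.sites["pos"] = positions
        m.sites["ref"], m.sites["alt"] = refs, alts
        return m

    def test_cognate_minus_strand_reported_as_a_to_g(self):
        m = self._matrix([3500], ["T"], ["C"])
        out = filtering.strand_filter(
            m, pd.DataFrame({"chrom": [], "pos": []}), _toy_annotation()
        )
        assert out.shape[0] == 1
        assert out.sites["gene_strand"].iloc[0] == "-"
        assert out.sites["canonical_ref"].iloc[0] == "A"
        assert out.sites["canonical_alt"].iloc[0] == "G"
        assert not out.sites["catalog_rescued"].iloc[0]

    def test_non_cognate_dropped(self):
        m = self._matrix([3500], ["A"], ["G"])  # A>G inside minus gene
        out = filtering.strand_filter(
            m, pd.DataFrame({"chrom": [], "pos": []}), _toy_annotation()
        )
        assert out.shape[0] == 0

    def test_overlap_region_dropped_unless_cataloged(self):
        m = self._matrix([5700, 5800], ["A", "A"], ["G", "G"])
        catalog = pd.DataFrame({"chrom": ["chr1"], "pos": [5800]})
        out = filtering.strand_filter(m, catalog, _toy_annotation())
        assert list(out.sites["pos"]) == [5800]
        assert out.sites["catalog_rescued"].iloc[0]

    def test_intergenic_uncataloged_dropped(self):
        m = self._matrix([2500], ["A"], ["G"])
        out = filtering.strand_filter(
            m, pd.DataFrame({"chrom": [], "pos": []}), _toy_annotation()
        )
        assert out.shape[0] == 0

    def test_missing_strand_raises_format_error(self):
        gff = pd.DataFrame(
            [("chr1", "sim", "gene", 1, 10, ".", ".", ".", "ID=g")],
            columns=["seqid", "source", "type", "start", "end", "score",
                     "strand", "phase", "attributes"],
        )
        with pytest.raises(FormatError, match="strand"):
            GenomeAnnotation(gff)


class TestContextAnnotation:
    def test_precedence_and_membership(self):
        repeats = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [100, 150],  # BED half-open; overlap at 150-199
                "end": [200, 300],
                "name": ["Alu", "repNonAlu"],
                "score": [0, 0],
                "strand": ["+", "+"],
            }
        )
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": [150, 180, 250, 400]}
        )  # 1-based: 180 is inside both intervals
        out = filtering.annotate_context(sites, repeats)
        assert list(out["context"]) == [
            "Alu", "Alu", "repNonAlu", "nonrepetitive"
        ]

    def test_matches_interval_oracle(self):
        rng = np.random.default_rng(1)
        starts = np.sort(rng.choice(100000, size=60, replace=False))
        repeats = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + rng.integers(50, 400, size=60),
                "name": rng.choice(["Alu", "repNonAlu"], size=60),
                "score": 0,
                "strand": "+",
            }
        )
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": rng.integers(1, 100001, size=1000)}
        )
        out = filtering.annotate_context(sites, repeats)
        for row in out.itertuples():
            p0 = row.pos - 1
            in_alu = (
                (repeats["name"] == "Alu")
                & (repeats["start"] <= p0)
                & (p0 < repeats["end"])
            ).any()
            in_rep = (
                (repeats["start"] <= p0) & (p0 < repeats["end"])
            ).any()
            expected = (
                "Alu" if in_alu else ("repNonAlu" if in_rep else
                                      "nonrepetitive")
            )
            assert row.context == expected


class TestFeatureAnnotation:
    def test_utr_exon_intron_other(self):
        ann = _toy_annotation()
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": [1950, 1100, 1500, 2500]}
        )
        out = filtering.annotate_feature(sites, ann)
        assert list(out["feature"]) == ["3'UTR", "exon", "intron", "other"]

    def test_matches_interval_oracle(self, small_dataset):
        ann = GenomeAnnotation(small_dataset.annotation.features)
        feats = small_dataset.annotation.features
        sites = small_dataset.truth.site_table.head(100)
        out = filtering.annotate_feature(sites, ann)
        order = [
            ("stop_codon", "stop_codon"),
            ("three_prime_UTR", "3'UTR"),
            ("five_prime_UTR", "5'UTR"),
            ("exon", "exon"),
        ]
        for row in out.itertuples():
            expected = None
            for ftype, label in order:
                sub = feats[feats["type"] == ftype]
                if (
                    (sub["seqid"] == row.chrom)
                    & (sub["start"] <= row.pos)
                    & (row.pos <= sub["end"])
                ).any():
                    expected = label
                    break
            if expected is None:
                genes = feats[feats["type"] == "gene"]
                inside = (
                    (genes["seqid"] == row.chrom)
                    & (genes["start"] <= row.pos)
                    & (row.pos <= genes["end"])
                ).any()
                expected = "intron" if inside else "other"
            assert row.feature == expected


class TestNovelty:
    def test_membership_combinations_match_set_algebra(self):
        rng = np.random.default_rng(3)
        pos = np.arange(1, 101) * 10
        sites = pd.DataFrame({"chrom": "chr1", "pos": pos})
        in_a = rng.random(100) < 0.5
        in_b = rng.random(100) < 0.3
        cat_a = pd.DataFrame({"chrom": "chr1", "pos": pos[in_a]})
        cat_b = pd.DataFrame({"chrom": "chr1", "pos": pos[in_b]})
        out = filtering.classify_novelty(sites, {"A": cat_a, "B": cat_b})
        assert (out["in_A"].to_numpy() == in_a).all()
        assert (out["in_B"].to_numpy() == in_b).all()
        assert (out["novel"].to_numpy() == (~in_a & ~in_b)).all()
        counts = {
            (a, b): int(((out["in_A"] == a) & (out["in_B"] == b)).sum())
            for a in (True, False)
            for b in (True, False)
        }
        assert sum(counts.values()) == 100
        assert counts[(True, True)] == int((in_a & in_b).sum())

    def test_requires_a_catalog(self):
        with pytest.raises(ValueError):
            filtering.classify_novelty(
                pd.DataFrame({"chrom": [], "pos": []}), {}
            )


class TestNeighborDistances:
    def test_pair_distance(self):
        sites = pd.DataFrame(
            {"chrom": "chr1", "context": "Alu", "pos": [100, 112]}
        )
        out = filtering.neighbor_distances(sites)
        assert list(out["nearest_distance"]) == [12, 12]

    def test_singleton_context_excluded(self):
        sites = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "context": ["Alu", "Alu", "nonrepetitive"],
                "pos": [100, 112, 500],
            }
        )
        out = filtering.neighbor_distances(sites)
        assert set(out["context"]) == {"Alu"}

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(9)
        sites = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], size=200),
                "context": rng.choice(["Alu", "nonrepetitive"], size=200),
                "pos": rng.choice(100000, size=200, replace=False),
            }
        )
        out = filtering.neighbor_distances(sites)
        lookup = {
            (r.chrom, r.context, r.pos): r.nearest_distance
            for r in out.itertuples()
        }
        for row in sites.itertuples():
            same = sites[
                (sites["chrom"] == row.chrom)
                & (sites["context"] == row.context)
                & (sites["pos"] != row.pos)
            ]
            if len(same) == 0:
                assert (row.chrom, row.context, row.pos) not in lookup
            else:
                expected = int(np.abs(same["pos"] - row.pos).min())
                assert lookup[(row.chrom, row.context, row.pos)] == expected


class TestCascadeOrder:
    def test_snp_and_strand_steps_commute(self, small_dataset):
        ds = small_dataset
        ann = GenomeAnnotation(ds.annotation.features)
        qc = filtering.cell_qc(ds.matrix.cells)
        cand = filtering.select_candidates(
            ds.matrix.subset_cells(qc["qc_pass"].to_numpy())
        )
        a, _ = filtering.remove_common_snps(cand, ds.annotation.snps)
        a = filtering.strand_filter(a, ds.annotation.catalog, ann)
        b = filtering.strand_filter(cand, ds.annotation.catalog, ann)
        b, _ = filtering.remove_common_snps(b, ds.annotation.snps)
        assert set(a.sites["site_id"]) == set(b.sites["site_id"])

    def test_every_retained_site_satisfies_thresholds(self, small_dataset):
        ds = small_dataset
        ann = GenomeAnnotation(ds.annotation.features)
        result = filtering.run_filter_cascade(
            ds.matrix,
            snps=ds.annotation.snps,
            catalog=ds.annotation.catalog,
            annotation=ann,
            repeats=ds.annotation.repeats,
        )
        m = result.matrix
        alt = m.alt.toarray()
        depth = m.depth.toarray()
        n_qual = ((depth >= 5) & (alt >= 2)).sum(axis=1)
        assert (n_qual >= 10).all()

    def test_replication_threshold_variant(self, small_dataset):
        # the lower-prevalence configuration (>=3 nuclei) retains a
        # superset of the default (>=10 nuclei) candidate set
        ds = small_dataset
        qc = filtering.cell_qc(ds.matrix.cells)
        passing = ds.matrix.subset_cells(qc["qc_pass"].to_numpy())
        strict = filtering.select_candidates(passing, min_cells=10)
        loose = filtering.select_candidates(passing, min_cells=3)
        assert set(strict.sites["site_id"]) <= set(loose.sites["site_id"])
        assert loose.shape[0] >= strict.shape[0]
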