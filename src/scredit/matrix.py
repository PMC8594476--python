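"""Aligned site x cell allele-count container.

``EditingMatrix`` pairs an alternate(-edited)-allele count matrix with a
total-depth matrix sharing one sparsity pattern, so a stored explicit
zero in ``alt`` at a position where ``depth`` > 0 means "transcribed but
unedited", while an absent entry means "not transcribed".  Site and cell
metadata travel with the matrices.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


@dataclasses.dataclass
class EditingMatrix:
    """Site-by-cell edited-allele counts and total depths.

    Attributes
    ----------
    sites : pandas.DataFrame
        One row per site; at minimum columns chrom, pos, ref, alt.
    cells : pandas.DataFrame
        One row per cell; at minimum column cell_id.
    alt : scipy.sparse.csr_matrix
        Edited (alternate) allele read counts, shape (n_sites, n_cells).
    depth : scipy.sparse.csr_matrix
        Total read depth; 0 (absent entry) = not transcribed.
    """

    sites: pd.DataFrame
    cells: pd.DataFrame
    alt: sp.csr_matrix
    depth: sp.csr_matrix

    def __post_init__(self) -> None:
        self.alt = sp.csr_matrix(self.alt)
        self.depth = sp.csr_matrix(self.depth)
        if self.alt.shape != self.depth.shape:
            raise ValueError("alt and depth must share shape")
        if self.alt.shape != (len(self.sites), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.alt.shape} does not match metadata "
                f"({len(self.sites)} sites, {len(self.cells)} cells)"
            )
        self._align()
        if (self.alt.data > self.depth.data).any():
            raise ValueError("alt count exceeds depth")
        self.sites = self.sites.reset_index(drop=True)
        self.cells = self.cells.reset_index(drop=True)

    def _align(self) -> None:
        """Force alt onto depth's sparsity pattern (alt <= depth implies
        alt's support is a subset of depth's)."""
        d = self.depth.tocsr()
        d.sort_indices()
        a = self.alt.tocsr()
        a.sort_indices()
        if np.array_equal(a.indptr, d.indptr) and np.array_equal(
            a.indices, d.indices
        ):
            self.alt, self.depth = a, d
            return
        # project alt entries onto depth pattern via row-major linear index
        ncol = d.shape[1]
        dcoo = d.tocoo()
        dlin = dcoo.row.astype(np.int64) * ncol + dcoo.col
        acoo = a.tocoo()
        alin = acoo.row.astype(np.int64) * ncol + acoo.col
        if len(dlin) == 0:
            pos_clipped = np.zeros(len(alin), dtype=np.intp)
            inside = np.zeros(len(alin), dtype=bool)
        else:
            pos = np.searchsorted(dlin, alin)
            pos_clipped = np.minimum(pos, len(dlin) - 1)
            inside = dlin[pos_clipped] == alin
        if (acoo.data[~inside] != 0).any():
            raise ValueError("alt entry outside depth support")
        data = np.zeros(len(dlin), dtype=a.dtype)
        data[pos_clipped[inside]] = acoo.data[inside]
        self.alt = sp.csr_matrix(
            (data, d.indices.copy(), d.indptr.copy()), shape=d.shape
        )
        self.depth = d

    # -- basic views ---------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.alt.shape

    def aligned_data(self):
        """(alt_data, depth_data, indices, indptr) on the shared pattern."""
        return (
            self.alt.data,
            self.depth.data,
            self.alt.indices,
            self.alt.indptr,
        )

    def fractions(self) -> sp.csr_matrix:
        """Edited-allele fraction at transcribed entries (same pattern)."""
        out = self.depth.copy().astype(float)
        out.data = self.alt.data / self.depth.data
        return out

    def subset_sites(self, mask) -> "EditingMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return EditingMatrix(
            self.sites.iloc[idx].reset_index(drop=True),
            self.cells,
            self.alt[idx],
            self.depth[idx],
        )

    def subset_cells(self, mask) -> "EditingMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return EditingMatrix(
            self.sites,
            self.cells.iloc[idx].reset_index(drop=True),
            self.alt[:, idx],
            self.depth[:, idx],
        )

    # -- persistence ---------------------------------------------------
    def to_dir(self, outdir) -> None:
        """Write MTX pair plus site/cell index TSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(outdir / "alt.mtx"), self.alt.tocoo())
        mmwrite(str(outdir / "depth.mtx"), self.depth.tocoo())
        self.sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)
        self.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, indir) -> "EditingMatrix":
        indir = Path(indir)
        sites = pd.read_csv(indir / "sites.tsv", sep="\t")
        cells = pd.read_csv(indir / "cells.tsv", sep="\t")
        alt = sp.csr_matrix(mmread(str(indir / "alt.mtx")))
        depth = sp.csr_matrix(mmread(str(indir / "depth.mtx")))
        return cls(sites, cells, alt, depth)
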