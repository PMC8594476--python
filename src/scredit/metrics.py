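"""Per-cell editing indices and group comparisons.

The global editing index (GEI) of a cell is the unweighted mean minor
(G) allele frequency over candidate editing sites transcribed in that
cell.  The Alu editing index (AEI) restricts to Alu-context sites, and
the stringent AEI further to Alu sites transcribed in at least 100
cells.  Cells transcribing no eligible site get a missing index, never
zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm

from scredit.matrix import EditingMatrix

MODES = ("GEI", "AEI", "stringentAEI")
STRINGENT_MIN_CELLS = 100


def _mode_site_mask(matrix: EditingMatrix, mode: str) -> np.ndarray:
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    n_sites = matrix.shape[0]
    if mode == "GEI":
        return np.ones(n_sites, dtype=bool)
    if "context" not in matrix.sites.columns:
        raise ValueError("AEI modes require a 'context' site column")
    alu = (matrix.sites["context"] == "Alu").to_numpy()
    if mode == "AEI":
        return alu
    transcribed_cells = np.asarray(
        (matrix.depth > 0).sum(axis=1)
    ).ravel()
    return alu & (transcribed_cells >= STRINGENT_MIN_CELLS)


def per_cell_indices(matrix: EditingMatrix, mode: str = "GEI") -> pd.DataFrame:
    """Per-cell editing summary for one index mode.

    Returns cell_id, n_transcribed, n_edited, and the index (NaN when no
    eligible site is transcribed in the cell).
    """
    mask = _mode_site_mask(matrix, mode)
    sub = matrix.subset_sites(mask) if not mask.all() else matrix
    frac = sub.fractions().tocsc()
    depth = sub.depth.tocsc()
    alt = sub.alt.tocsc()
    n_cells = sub.shape[1]
    n_transcribed = np.zeros(n_cells, dtype=int)
    n_edited = np.zeros(n_cells, dtype=int)
    index = np.full(n_cells, np.nan)
    for j in range(n_cells):
        sl = slice(depth.indptr[j], depth.indptr[j + 1])
        d = depth.data[sl]
        covered = d > 0
        n_transcribed[j] = int(covered.sum())
        if n_transcribed[j] == 0:
            continue
        a = alt.data[sl][covered]
        n_edited[j] = int((a >= 1).sum())
        index[j] = float(frac.data[sl][covered].mean())
    out = pd.DataFrame(
        {
            "cell_id": sub.cells["cell_id"].to_numpy(),
            "n_transcribed": n_transcribed,
            "n_edited": n_edited,
            mode: index,
        }
    )
    return out


def all_cell_indices(matrix: EditingMatrix) -> pd.DataFrame:
    """GEI, AEI and stringent AEI in one table."""
    out = per_cell_indices(matrix, "GEI")
    for mode in ("AEI", "stringentAEI"):
        out[mode] = per_cell_indices(matrix, mode)[mode]
    return out


def per_site_summaries(matrix: EditingMatrix) -> pd.DataFrame:
    """Per-site transcription prevalence, edited-cell count and mean
    minor-allele frequency over transcribed cells.

    'Edited in a cell' means alternate count >= 1 at a transcribed
    site.  Sites transcribed nowhere are excluded.
    """
    alt_d, depth_d, _, indptr = matrix.aligned_data()
    covered = depth_d > 0
    frac = np.where(covered, alt_d / np.maximum(depth_d, 1), 0.0)
    n = matrix.shape[0]
    n_tr = np.zeros(n, dtype=int)
    n_ed = np.zeros(n, dtype=int)
    mean_maf = np.full(n, np.nan)
    for i in range(n):
        sl = slice(indptr[i], indptr[i + 1])
        c = covered[sl]
        n_tr[i] = int(c.sum())
        if n_tr[i]:
            n_ed[i] = int((alt_d[sl][c] >= 1).sum())
            mean_maf[i] = float(frac[sl][c].mean())
    out = matrix.sites.copy()
    out["n_transcribed"] = n_tr
    out["n_edited"] = n_ed
    out["mean_maf"] = mean_maf
    return out[n_tr > 0].reset_index(drop=True)


def per_site_cell_fractions(matrix: EditingMatrix) -> np.ndarray:
    """Flat array of per-(site, cell) edited fractions at transcribed
    entries — the distribution whose bimodality the study conditions
    posit."""
    alt_d, depth_d, _, _ = matrix.aligned_data()
    covered = depth_d > 0
    return alt_d[covered] / depth_d[covered]


def compare_indices(
    summaries: pd.DataFrame,
    cells: pd.DataFrame,
    grouping: str = "phenotype",
    index_col: str = "GEI",
) -> pd.DataFrame:
    """Linear model of a per-cell index on group indicators plus log10
    library size.

    ``grouping`` is 'phenotype', 'subgroup' or 'region_x_phenotype'.
    Returns the coefficient table (term, effect, se, t, p).
    """
    df = summaries.merge(cells, on="cell_id")
    df = df.dropna(subset=[index_col])
    if grouping == "region_x_phenotype":
        df["_group"] = df["region"].astype(str) + ":" + df["phenotype"].astype(str)
    elif grouping in df.columns:
        df["_group"] = df[grouping].astype(str)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    levels = sorted(df["_group"].unique())
    if len(levels) < 2:
        raise ValueError(
            f"need >= 2 groups to compare, got {levels!r}"
        )
    counts = df["_group"].value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with < 2 cells: {small}")
    dummies = pd.get_dummies(df["_group"], drop_first=True, dtype=float)
    dummies.columns = [f"group[{c}]" for c in dummies.columns]
    X = pd.concat(
        [
            pd.Series(1.0, index=df.index, name="intercept"),
            dummies,
            np.log10(df["library_size"]).rename("log10_library_size"),
        ],
        axis=1,
    )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by incremental rank
        aliased = []
        cols: list[str] = []
        for c in X.columns:
            trial = X[cols + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(cols):
                aliased.append(c)
            else:
                cols.append(c)
        raise ValueError(f"singular design; aliased terms: {aliased}")
    fit = sm.OLS(df[index_col].to_numpy(), X.to_numpy()).fit()
    return pd.DataFrame(
        {
            "term": X.columns,
            "effect": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )


_ = sp  # scipy.sparse types appear in signatures at runtime
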