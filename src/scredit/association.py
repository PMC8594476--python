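"""Gene abundance - editing association models.

Per gene, the per-cell global editing index is regressed on log10
transcripts-per-million over the cells expressing the gene, controlling
for gross neuronal phenotype and log10 library size.  Benjamini-
Hochberg FDR is applied across genes, and a gene is called significant
when FDR < 0.05 and |beta| > 0.01 (beta = change in editing index per
decade of abundance).  A downsampling check refits widely expressed
genes on a capped random subsample of cells to guard against
sample-size artifacts, and association profiles from two data sets can
be compared by correlating per-gene betas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_CELLS_EXPR_DEFAULT = 300


def _fit_one_gene(
    gei: np.ndarray,
    log10_tpm: np.ndarray,
    phenotype_ind: np.ndarray,
    log10_lib: np.ndarray,
) -> tuple[float, float, float, int]:
    """OLS of editing index on log10 TPM + phenotype + log10 library
    size.  Returns (beta, se, p, n)."""
    n = len(gei)
    X = np.column_stack(
        [np.ones(n), log10_tpm, phenotype_ind, log10_lib]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return np.nan, np.nan, np.nan, n
    coef, res, _rank, _sv = np.linalg.lstsq(X, gei, rcond=None)
    fitted = X @ coef
    rss = float(((gei - fitted) ** 2).sum())
    df = n - X.shape[1]
    if df <= 0:
        return np.nan, np.nan, np.nan, n
    sigma2 = rss / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    beta = float(coef[1])
    if se == 0:
        return beta, se, np.nan, n
    t = beta / se
    p = float(2 * stats.t.sf(abs(t), df))
    return beta, se, p, n


def fit_gene_associations(
    summaries: pd.DataFrame,
    tpm: pd.DataFrame,
    cells: pd.DataFrame,
    min_cells_expr: int = MIN_CELLS_EXPR_DEFAULT,
    fdr: float = 0.05,
    beta_min: float = 0.01,
    index_col: str = "GEI",
) -> pd.DataFrame:
    """Per-gene abundance-editing association table.

    ``tpm`` is gene-by-cell; only cells with TPM > 0 enter a gene's
    model (the expression predictor is log10 TPM on expressing cells).
    Genes expressed in fewer than ``min_cells_expr`` eligible cells, or
    with constant abundance, are skipped and reported with a reason.
    """
    meta = summaries.merge(cells, on="cell_id").dropna(subset=[index_col])
    meta = meta.set_index("cell_id")
    shared = [c for c in tpm.columns if c in meta.index]
    meta = meta.loc[shared]
    phen_levels = sorted(meta["phenotype"].astype(str).unique())
    phen_ind = (
        meta["phenotype"].astype(str) == phen_levels[-1]
    ).to_numpy(dtype=float)
    gei = meta[index_col].to_numpy(dtype=float)
    log10_lib = np.log10(meta["library_size"].to_numpy(dtype=float))
    expr = tpm[shared].to_numpy(dtype=float)

    rows = []
    for gi, gene in enumerate(tpm.index):
        x = expr[gi]
        pos = x > 0
        n_expr = int(pos.sum())
        if n_expr < min_cells_expr:
            rows.append((gene, np.nan, np.nan, np.nan, n_expr, "too_few_cells"))
            continue
        lx = np.log10(x[pos])
        if np.ptp(lx) == 0:
            rows.append((gene, np.nan, np.nan, np.nan, n_expr, "constant_tpm"))
            continue
        beta, se, p, n = _fit_one_gene(
            gei[pos], lx, phen_ind[pos], log10_lib[pos]
        )
        reason = "" if np.isfinite(p) else "singular"
        rows.append((gene, beta, se, p, n, reason))
    out = pd.DataFrame(
        rows, columns=["gene_id", "beta", "se", "p", "n_cells_expr", "skipped"]
    )
    tested = out["p"].notna()
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = multipletests(
            out.loc[tested, "p"].to_numpy(), method="fdr_bh"
        )[1]
    out["significant"] = (
        tested
        & (out["fdr"] < fdr)
        & (out["beta"].abs() > beta_min)
    )
    out["downsampled"] = False
    return out


def downsample_check(
    results: pd.DataFrame,
    summaries: pd.DataFrame,
    tpm: pd.DataFrame,
    cells: pd.DataFrame,
    cap: int = 1500,
    seed: int = 0,
    min_cells_expr: int = MIN_CELLS_EXPR_DEFAULT,
    fdr: float = 0.05,
    beta_min: float = 0.01,
    index_col: str = "GEI",
) -> pd.DataFrame:
    """Refit genes expressed in more than ``cap`` cells on a seeded
    random subsample of ``cap`` expressing cells.

    Returns the refit table with ``downsampled`` flags plus sign- and
    significance-concordance columns against the full fit.  Genes at or
    under the cap are carried over untouched.
    """
    rng = np.random.default_rng(seed)
    meta = summaries.merge(cells, on="cell_id").dropna(subset=[index_col])
    meta = meta.set_index("cell_id")
    shared = [c for c in tpm.columns if c in meta.index]
    meta = meta.loc[shared]
    phen_levels = sorted(meta["phenotype"].astype(str).unique())
    phen_ind = (
        meta["phenotype"].astype(str) == phen_levels[-1]
    ).to_numpy(dtype=float)
    gei = meta[index_col].to_numpy(dtype=float)
    log10_lib = np.log10(meta["library_size"].to_numpy(dtype=float))
    expr = tpm[shared].to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(tpm.index)}

    out = results.copy()
    for col in ("beta_ds", "p_ds", "fdr_ds"):
        out[col] = np.nan
    for ridx, row in out.iterrows():
        gi = gene_pos.get(row["gene_id"])
        if gi is None or not np.isfinite(row["p"]):
            continue
        x = expr[gi]
        pos = np.flatnonzero(x > 0)
        if len(pos) <= cap:
            out.loc[ridx, "beta_ds"] = row["beta"]
            out.loc[ridx, "p_ds"] = row["p"]
            continue
        sub = rng.choice(pos, size=cap, replace=False)
        lx = np.log10(x[sub])
        if np.ptp(lx) == 0 or len(sub) < min_cells_expr:
            continue
        beta, _se, p, _n = _fit_one_gene(
            gei[sub], lx, phen_ind[sub], log10_lib[sub]
        )
        out.loc[ridx, ["beta_ds", "p_ds"]] = beta, p
        out.loc[ridx, "downsampled"] = True
    tested = out["p_ds"].notna()
    if tested.any():
        out.loc[tested, "fdr_ds"] = multipletests(
            out.loc[tested, "p_ds"].to_numpy(), method="fdr_bh"
        )[1]
    out["significant_ds"] = (
        tested & (out["fdr_ds"] < fdr) & (out["beta_ds"].abs() > beta_min)
    )
    out["sign_concordant"] = np.sign(out["beta"]) == np.sign(out["beta_ds"])
    return out


def cross_dataset_beta_correlation(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    subset: pd.DataFrame | None = None,
) -> dict:
    """Pearson correlation of shared-gene association betas across two
    data sets, optionally with a labeled prior subset.

    ``subset``, if given, has columns gene_id and label (e.g.
    'positive'/'negative' from an external reference); the subset
    correlation is computed on those genes, and a Mann-Whitney test of
    beta separation between the two labels is reported per data set.
    """
    merged = results_a.merge(
        results_b, on="gene_id", suffixes=("_a", "_b")
    ).dropna(subset=["beta_a", "beta_b"])
    if len(merged) < 3:
        raise ValueError(
            f"need >= 3 shared genes with fitted betas, got {len(merged)}"
        )
    r, p = stats.pearsonr(merged["beta_a"], merged["beta_b"])
    out = {"r": float(r), "p": float(p), "n_shared": int(len(merged))}
    if subset is not None:
        sub = merged.merge(subset, on="gene_id")
        if len(sub) >= 3:
            rs, ps = stats.pearsonr(sub["beta_a"], sub["beta_b"])
            out["subset_r"], out["subset_p"] = float(rs), float(ps)
            out["n_subset"] = int(len(sub))
            labels = sorted(sub["label"].unique())
            if len(labels) == 2:
                g0 = sub[sub["label"] == labels[0]]
                g1 = sub[sub["label"] == labels[1]]
                for tag in ("a", "b"):
                    if len(g0) and len(g1):
                        stat, mw_p = stats.mannwhitneyu(
                            g0[f"beta_{tag}"],
                            g1[f"beta_{tag}"],
                            alternative="two-sided",
                        )
                        out[f"separation_p_{tag}"] = float(mw_p)
    return out
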