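"""Pseudobulk differential editing between cell groups.

Single-cell editing signals are summed into pseudobulk replicates, one
per (subgroup, region) combination, as paired edited / unedited allele
counts.  Site-level differences between phenotypes are tested with a
negative-binomial generalized linear model on the paired counts — the
differential-methylation adaptation of count-based expression modeling:
each pseudobulk sample contributes two observations (edited, unedited)
tied by a sample blocking term, and the coefficient of interest is the
contrast x editing-status interaction, i.e. the log fold-change of
editing odds between groups, with coverage entering naturally through
the counts.  Gene-level directional enrichment uses a rotation test on
per-sample logit editing proportions, which yields continuous null
p-values even with a handful of pseudobulk samples.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from scredit.matrix import EditingMatrix

DISPERSION_PRIOR_DF = 20.0


@dataclasses.dataclass
class PseudobulkTable:
    """Per-sample summed edited / unedited counts per site.

    ``edited`` and ``unedited`` have shape (n_sites, n_samples);
    ``samples`` carries subgroup, region, phenotype and the number of
    cells aggregated; ``sites`` is the retained site metadata.
    """

    edited: np.ndarray
    unedited: np.ndarray
    samples: pd.DataFrame
    sites: pd.DataFrame
    n_removed_low_variance: int = 0


def build_pseudobulk(
    matrix: EditingMatrix,
    group_by: tuple = ("subgroup", "region"),
    var_min: float = 0.2,
    var_on: str = "counts",
) -> PseudobulkTable:
    """Aggregate cells into pseudobulk samples and filter invariant sites.

    Sites whose sample variance of edited counts across pseudobulk
    samples (``var_on='counts'``) — or of the editing fraction
    (``var_on='fraction'``) — is <= ``var_min`` are removed.
    """
    cells = matrix.cells
    for col in group_by:
        if col not in cells.columns:
            raise ValueError(f"cells table lacks grouping column {col!r}")
    key = cells[list(group_by)].astype(str).agg("|".join, axis=1)
    groups = sorted(key.unique())
    if not groups:
        raise ValueError("no cells to aggregate")
    edited_cols, sample_rows = [], []
    alt_csr, depth_csr = matrix.alt, matrix.depth
    unedited_cols = []
    for g in groups:
        idx = np.flatnonzero((key == g).to_numpy())
        if len(idx) == 0:  # pragma: no cover - groups derive from cells
            warnings.warn(f"pseudobulk group {g} has no cells; dropped")
            continue
        e = np.asarray(alt_csr[:, idx].sum(axis=1)).ravel()
        tot = np.asarray(depth_csr[:, idx].sum(axis=1)).ravel()
        edited_cols.append(e)
        unedited_cols.append(tot - e)
        grp_cells = cells.iloc[idx]
        row = dict(zip(group_by, g.split("|")))
        row["sample_id"] = g
        row["n_cells"] = len(idx)
        if "phenotype" in cells.columns:
            row["phenotype"] = grp_cells["phenotype"].iloc[0]
        sample_rows.append(row)
    edited = np.column_stack(edited_cols).astype(np.int64)
    unedited = np.column_stack(unedited_cols).astype(np.int64)
    samples = pd.DataFrame(sample_rows)
    if edited.shape[1] < 2:
        # variance across pseudoreplicates is undefined with one sample
        v = np.full(edited.shape[0], np.inf)
    elif var_on == "counts":
        v = edited.var(axis=1, ddof=1)
    elif var_on == "fraction":
        tot = edited + unedited
        frac = np.divide(
            edited, tot, out=np.zeros_like(edited, dtype=float),
            where=tot > 0,
        )
        v = frac.var(axis=1, ddof=1)
    else:
        raise ValueError(f"var_on must be 'counts' or 'fraction', got {var_on!r}")
    keep = v > var_min
    return PseudobulkTable(
        edited=edited[keep],
        unedited=unedited[keep],
        samples=samples,
        sites=matrix.sites[keep].reset_index(drop=True),
        n_removed_low_variance=int((~keep).sum()),
    )


# ---------------------------------------------------------------------------
# Site-level NB paired-count models
# ---------------------------------------------------------------------------

def _paired_design(
    samples: pd.DataFrame, contrast: str, adjust: str | None
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Long-format design for paired (edited, unedited) counts.

    Rows are ordered (sample0-unedited, sample0-edited, sample1-...).
    Columns: one blocking indicator per sample, the editing-status
    indicator, status x adjust terms, and last the status x contrast
    interaction (log editing-odds ratio between contrast levels).
    """
    G = len(samples)
    levels = sorted(samples[contrast].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(
            f"contrast {contrast!r} must have 2 levels, got {levels}"
        )
    status = np.tile([0.0, 1.0], G)
    block = np.kron(np.eye(G), np.ones(2)[:, None]).reshape(2 * G, G)
    cols = [f"sample[{s}]" for s in samples["sample_id"]]
    X = [block, status[:, None]]
    cols.append("status")
    if adjust is not None:
        adj_levels = sorted(samples[adjust].astype(str).unique())
        for lv in adj_levels[1:]:
            ind = (samples[adjust].astype(str) == lv).to_numpy().astype(float)
            X.append((np.repeat(ind, 2) * status)[:, None])
            cols.append(f"status:{adjust}[{lv}]")
    contrast_ind = (
        samples[contrast].astype(str) == levels[1]
    ).to_numpy().astype(float)
    X.append((np.repeat(contrast_ind, 2) * status)[:, None])
    cols.append(f"status:{contrast}[{levels[1]}]")
    return np.hstack(X), cols, status


def _moment_alpha(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Method-of-moments NB dispersion from a Poisson fit:
    E[(y-mu)^2] = mu + alpha mu^2."""
    df = len(y) - n_params
    if df <= 0:
        return 0.0
    contrib = ((y - mu) ** 2 - mu) / np.maximum(mu, 1e-8) ** 2
    return float(max(0.0, contrib.sum() / df))


def fit_site_models(
    pb: PseudobulkTable,
    contrast: str = "phenotype",
    adjust: str | None = "region",
    prior_df: float = DISPERSION_PRIOR_DF,
) -> pd.DataFrame:
    """Per-site NB quasi-likelihood tests of differential editing.

    A common NB dispersion (method of moments over per-site Poisson
    fits, median across sites) captures the mean-variance trend; each
    site then gets a quasi-dispersion scale from its NB Pearson
    statistic, squeezed toward the across-site median with ``prior_df``
    weight, and a moderated t reference with ``prior_df`` + residual
    degrees of freedom — the few-replicate regime this data lives in.
    Returns log2 fold-change of editing odds between contrast levels
    (second sorted level vs first), moderated t, two-sided p and BH FDR
    over all tested sites.  Sites where a whole arm (all edited or all
    unedited counts of one contrast level) is zero get 0.5 added to
    every count and are flagged ``continuity``.
    """
    for level in sorted(pd.unique(pb.samples[contrast].astype(str))):
        if (pb.samples[contrast].astype(str) == level).sum() < 2:
            raise ValueError(
                f"contrast level {level!r} has < 2 pseudoreplicates"
            )
    X, cols, _status = _paired_design(pb.samples, contrast, adjust)
    n_params = X.shape[1]
    S = pb.edited.shape[0]
    contrast_levels = sorted(pb.samples[contrast].astype(str).unique())
    arm = (
        pb.samples[contrast].astype(str) == contrast_levels[1]
    ).to_numpy()

    # first pass: Poisson fits give the common NB dispersion
    ys, alphas, flags = [], np.zeros(S), np.zeros(S, dtype=bool)
    for i in range(S):
        e, u = pb.edited[i].astype(float), pb.unedited[i].astype(float)
        zero_arm = (
            e[arm].sum() == 0
            or e[~arm].sum() == 0
            or u[arm].sum() == 0
            or u[~arm].sum() == 0
        )
        if zero_arm:
            e, u = e + 0.5, u + 0.5
            flags[i] = True
        y = np.empty(2 * len(e))
        y[0::2], y[1::2] = u, e
        ys.append(y)
        try:
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            alphas[i] = _moment_alpha(y, fit.mu, n_params)
        except Exception:
            alphas[i] = 0.0
    common = max(float(np.median(alphas)), 1e-8) if S else 1e-8
    n_obs = X.shape[0]
    resid_df = max(1, n_obs - n_params)

    # second pass: NB fits at the common dispersion; per-site
    # quasi-dispersion from the Pearson statistic
    coefs = np.full(S, np.nan)
    ses = np.full(S, np.nan)
    phis = np.full(S, np.nan)
    fam = sm.families.NegativeBinomial(alpha=common)
    for i in range(S):
        try:
            fit = sm.GLM(ys[i], X, family=fam).fit()
            coefs[i] = fit.params[-1]
            ses[i] = fit.bse[-1]
            phis[i] = float((fit.resid_pearson**2).sum()) / resid_df
        except Exception:
            continue
    ok = np.isfinite(phis)
    phi0 = float(np.median(phis[ok])) if ok.any() else 1.0
    phi_sq = (prior_df * phi0 + resid_df * phis) / (prior_df + resid_df)
    phi_sq = np.maximum(phi_sq, 1e-3)
    total_df = prior_df + resid_df

    rows = []
    for i in range(S):
        coef, se = coefs[i], ses[i]
        if np.isfinite(coef) and np.isfinite(se) and se > 0:
            t = coef / (se * np.sqrt(phi_sq[i]))
            p = 2 * stats.t.sf(abs(t), total_df)
        else:
            t, p = np.nan, np.nan
        rows.append(
            {
                "log2fc": coef / np.log(2) if np.isfinite(coef) else np.nan,
                "se": se / np.log(2) if np.isfinite(se) else np.nan,
                "t": t,
                "p": p,
                "dispersion": common,
                "ql_scale": phi_sq[i],
                "continuity": flags[i],
            }
        )
    out = pd.concat(
        [pb.sites.reset_index(drop=True), pd.DataFrame(rows)], axis=1
    )
    ok = out["p"].notna()
    fdr = np.full(len(out), np.nan)
    if ok.any():
        fdr[ok.to_numpy()] = multipletests(
            out.loc[ok, "p"].to_numpy(), method="fdr_bh"
        )[1]
    out["fdr"] = fdr
    out.attrs["contrast_levels"] = contrast_levels
    return out


# ---------------------------------------------------------------------------
# Gene-level directional rotation test
# ---------------------------------------------------------------------------

def _logit_proportions(pb: PseudobulkTable) -> np.ndarray:
    e = pb.edited.astype(float)
    u = pb.unedited.astype(float)
    return np.log((e + 0.5) / (u + 0.5))


def _sample_design(
    samples: pd.DataFrame, contrast: str, adjust: str | None
) -> np.ndarray:
    levels = sorted(samples[contrast].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(
            f"contrast {contrast!r} must have 2 levels, got {levels}"
        )
    G = len(samples)
    cols = [np.ones(G)]
    if adjust is not None:
        for lv in sorted(samples[adjust].astype(str).unique())[1:]:
            cols.append(
                (samples[adjust].astype(str) == lv).to_numpy().astype(float)
            )
    cols.append(
        (samples[contrast].astype(str) == levels[1]).to_numpy().astype(float)
    )
    return np.column_stack(cols)


def gene_directional_test(
    pb: PseudobulkTable,
    gene_col: str = "gene_id",
    contrast: str = "phenotype",
    adjust: str | None = "region",
    min_sites: int = 2,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Directional gene-set enrichment by residual rotation.

    Per site, an ordinary t-statistic of the contrast coefficient is
    computed from the per-sample logit editing proportions; the gene
    statistic is the mean site t.  The null rotates each site's
    (effect, residual) vector with an independent uniform rotation —
    under spherically symmetric residuals the rotated t-statistic is
    exactly Student-t with the model's residual degrees of freedom,
    regardless of the site's magnitude, so the rotation null of the
    gene mean is sampled directly from independent t draws.  Sites are
    treated as conditionally independent given the pseudobulk design
    (residual noise is site-level sampling noise).  Two one-sided
    rotation p-values are combined into a direction and p, with BH FDR
    across genes.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100 (unstable null), got {n_perm}")
    if gene_col not in pb.sites.columns:
        raise ValueError(f"sites table lacks gene column {gene_col!r}")
    X = _sample_design(pb.samples, contrast, adjust)
    G, p = X.shape
    d = G - p
    if d < 1:
        raise ValueError("no residual degrees of freedom for rotation")
    Y = _logit_proportions(pb)  # (S, G)
    beta, _res, _rank, _sv = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    rss = ((Y - fitted) ** 2).sum(axis=1)
    xtx_inv_cc = np.linalg.inv(X.T @ X)[-1, -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(rss, 1e-300) / d * xtx_inv_cc)
        t_obs = np.where(rss > 0, beta[-1] / se, 0.0)

    rng = np.random.default_rng(seed)
    genes = pb.sites[gene_col].astype(str)
    rows = []
    for gene, idx in genes.groupby(genes).groups.items():
        ii = np.asarray(idx)
        if len(ii) < min_sites:
            continue
        T = float(t_obs[ii].mean())
        Tnull = rng.standard_t(d, size=(n_perm, len(ii))).mean(axis=1)
        p_up = (1 + (Tnull >= T).sum()) / (n_perm + 1)
        p_dn = (1 + (Tnull <= T).sum()) / (n_perm + 1)
        rows.append(
            {
                "gene_id": gene,
                "n_sites": int(len(ii)),
                "stat": T,
                "direction": "up" if p_up <= p_dn else "down",
                "p": min(1.0, 2 * min(p_up, p_dn)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["fdr"] = pd.Series(dtype=float)
    levels = sorted(pb.samples[contrast].astype(str).unique())
    out.attrs["direction_up_means"] = f"more editing in {levels[1]}"
    return out


# ---------------------------------------------------------------------------
# Disease-site overlap
# ---------------------------------------------------------------------------

def disease_overlap_test(
    sites: pd.DataFrame,
    disease_flag: str,
    biased_genes: set,
    gene_col: str = "gene_id",
) -> dict:
    """Fisher's exact test of disease-site membership against
    membership of direction-biased genes, over the whole site universe.

    Returns odds ratio, two-sided p, the 2x2 table and a degenerate
    flag (empty margin -> OR undefined, p = 1).
    """
    dis = sites[disease_flag].astype(bool).to_numpy()
    in_gene = sites[gene_col].astype(str).isin(set(biased_genes)).to_numpy()
    a = int((dis & in_gene).sum())
    b = int((dis & ~in_gene).sum())
    c = int((~dis & in_gene).sum())
    dd = int((~dis & ~in_gene).sum())
    table = [[a, b], [c, dd]]
    if min(a + b, c + dd, a + c, b + dd) == 0:
        return {
            "odds_ratio": np.nan,
            "p": 1.0,
            "table": table,
            "degenerate": True,
        }
    orat, pval = stats.fisher_exact(table, alternative="two-sided")
    return {
        "odds_ratio": float(orat),
        "p": float(pval),
        "table": table,
        "degenerate": False,
    }


_ = sp  # scipy.sparse appears in EditingMatrix signatures
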