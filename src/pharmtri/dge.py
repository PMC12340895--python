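"""Expression profiling: paired differential expression and spatial tests.

The bulk arm fits a per-gene negative-binomial GLM to paired brain-region
counts (cerebellum and DLPFC from the same subjects, cases and controls),
with subject blocking, median-of-ratios size factors, method-of-moments
dispersions shrunk halfway toward a fitted mean-dispersion trend, Wald
tests for the region, status, and region-by-status coefficients, and
Benjamini-Hochberg adjustment across genes.  The baseline is cerebellum in
control subjects; subject effects use sum-to-zero contrasts within each
status group so the status coefficient is a between-group mean contrast.

The spatial arm compares Q3 (upper-quartile) normalized expression between
diagnosis groups within fluorescently labeled cell types using pairwise
Wilcoxon rank-sum tests with BH correction.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "estimate_dispersions",
    "fit_paired_nb",
    "q3_normalize",
    "celltype_wilcoxon",
]

LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors per sample.

    The reference is the per-gene geometric mean over samples (genes with a
    zero anywhere are excluded from the reference, as their geometric mean
    is zero); each sample's factor is the median ratio to the reference.
    Identical samples all get factor 1.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    log_ref = np.log(mat[positive]).mean(axis=1)
    ratios = np.log(mat[positive]) - log_ref[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns,
                     name="size_factor")


def _mom_dispersion(norm_counts: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion on normalized counts."""
    mean = norm_counts.mean(axis=1)
    var = norm_counts.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean) / mean**2
    return np.where(np.isfinite(alpha), np.clip(alpha, 1e-8, None), 1e-8)


def estimate_dispersions(counts: pd.DataFrame, sf: pd.Series) -> pd.Series:
    """MoM dispersions shrunk 50% toward the fitted 1/mean trend.

    The trend ``alpha(mean) = a0 + a1/mean`` is fit by least squares across
    genes; the final dispersion is the arithmetic midpoint of the gene-wise
    estimate and the trend value at the gene's mean.
    """
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    mean = norm.mean(axis=1)
    alpha = _mom_dispersion(norm)
    ok = mean > 0
    A = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(A, alpha[ok], rcond=None)
    trend = np.clip(coef[0] + coef[1] / np.clip(mean, 1e-8, None), 1e-8, None)
    shrunk = 0.5 * alpha + 0.5 * trend
    return pd.Series(shrunk, index=counts.index, name="dispersion")


def _paired_design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept, status, region, interaction + sum-to-zero subject blocks."""
    required = {"sample", "subject", "region", "status"}
    if not required <= set(design.columns):
        raise ValueError(f"design needs columns {sorted(required)}")
    status = (design["status"] == "case").to_numpy(float)
    region = (design["region"] == "DLPFC").to_numpy(float)
    cols = [np.ones(len(design)), status, region, status * region]
    names = ["intercept", "status", "region", "interaction"]
    for grp in ("case", "control"):
        subjects = sorted(design.loc[design["status"] == grp, "subject"].unique())
        if len(subjects) < 2:
            raise ValueError(f"need >= 2 subjects with status {grp!r}")
        last = subjects[-1]
        for s in subjects[:-1]:
            col = np.where(design["subject"] == s, 1.0,
                           np.where(design["subject"] == last, -1.0, 0.0))
            cols.append(col)
            names.append(f"subject[{s}]")
    return np.column_stack(cols), names


def fit_paired_nb(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    *,
    bh_on: str = "interaction",
) -> pd.DataFrame:
    """Per-gene paired NB GLM Wald tests; returns a tidy results frame.

    Columns: log2fc_region / log2fc_status / log2fc_interaction with their
    SEs and Wald p-values (all on the log2 scale), the gene dispersion, and
    BH q-values across genes for the ``bh_on`` coefficient.
    """
    mat = counts.to_numpy()
    if not np.issubdtype(mat.dtype, np.integer):
        if not np.allclose(mat, np.round(mat)):
            raise ValueError("counts must be integers")
        mat = np.round(mat).astype(np.int64)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    design = design.set_index("sample").loc[counts.columns].reset_index()
    sf = size_factors(counts)
    disp = estimate_dispersions(counts, sf)
    X, names = _paired_design_matrix(design)
    offset = np.log(sf.to_numpy())
    rows = []
    for gi, gene in enumerate(counts.index):
        y = mat[gi]
        alpha = float(disp.iloc[gi])
        fam = sm.families.NegativeBinomial(alpha=alpha)
        try:
            res = sm.GLM(y, X, family=fam, offset=offset).fit()
            params, bse = res.params, res.bse
        except Exception:  # degenerate gene (e.g., all zeros)
            params = np.full(X.shape[1], np.nan)
            bse = np.full(X.shape[1], np.nan)
        row = {"gene": gene, "dispersion": alpha}
        for name in ("region", "status", "interaction"):
            j = names.index(name)
            row[f"log2fc_{name}"] = params[j] / LN2
            row[f"se_{name}"] = bse[j] / LN2
            z = params[j] / bse[j] if bse[j] > 0 else np.nan
            row[f"p_{name}"] = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene")
    pcol = f"p_{bh_on}"
    ok = out[pcol].notna()
    out["bh_q"] = np.nan
    if ok.any():
        out.loc[ok, "bh_q"] = multipletests(out.loc[ok, pcol], method="fdr_bh")[1]
    return out


def q3_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Upper-quartile normalization of a gene x ROI expression table.

    Each ROI (column) is divided by its 75th-percentile expression and
    rescaled by the geometric mean of the upper quartiles, so an ROI scaled
    by any constant has an unchanged normalized profile and all-equal ROIs
    pass through unchanged.  ROIs with a zero upper quartile are dropped.
    """
    q3 = expr.quantile(0.75, axis=0)
    keep = q3 > 0
    if not keep.all():
        expr = expr.loc[:, keep]
        q3 = q3[keep]
    if expr.shape[1] == 0:
        raise ValueError("all ROIs have zero upper-quartile expression")
    scale = float(np.exp(np.log(q3).mean()))
    return expr / q3 * scale


def _rank_sum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 30) -> float:
    if len(x) < 2 or len(y) < 2:
        return np.nan
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # all observations tied
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    exact = len(x) < exact_max_n and len(y) < exact_max_n and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(min(res.pvalue, 1.0))


def celltype_wilcoxon(
    norm_expr: pd.DataFrame,
    meta: pd.DataFrame,
    *,
    group_col: str = "diagnosis",
    cell_type_col: str = "cell_type",
) -> pd.DataFrame:
    """Pairwise rank-sum tests between diagnosis groups within cell types.

    ``norm_expr`` is gene x ROI (Q3-normalized); ``meta`` indexes ROIs with
    their diagnosis group and cell type.  The exact null distribution is
    used for group sizes below 30 without ties; the normal approximation
    with continuity correction otherwise; mid-ranks handle ties.  BH
    adjustment is applied within each cell type across genes and contrasts.
    Groups with fewer than two ROIs are skipped.
    """
    meta = meta.loc[norm_expr.columns]
    rows = []
    for ct, sub in meta.groupby(cell_type_col):
        groups = sorted(sub[group_col].unique())
        for g1, g2 in combinations(groups, 2):
            c1 = sub.index[sub[group_col] == g1]
            c2 = sub.index[sub[group_col] == g2]
            if len(c1) < 2 or len(c2) < 2:
                continue
            for gene in norm_expr.index:
                p = _rank_sum_p(norm_expr.loc[gene, c1].to_numpy(float),
                                norm_expr.loc[gene, c2].to_numpy(float))
                rows.append({"cell_type": ct, "gene": gene,
                             "contrast": f"{g1}_vs_{g2}", "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["bh_q"] = np.nan
    for ct, idx in out.groupby("cell_type").groups.items():
        ok = out.loc[idx, "p"].notna()
        sel = np.asarray(idx)[np.asarray(ok)]
        if len(sel):
            out.loc[sel, "bh_q"] = multipletests(out.loc[sel, "p"], method="fdr_bh")[1]
    return out
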