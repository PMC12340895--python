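"""Pharmagenic enrichment: gene statistics, gene-set tests, pathway scores.

SNPs are mapped to genes with strand-aware asymmetric windows (5 kb
upstream, 1.5 kb downstream of the gene body).  A gene's association
statistic at a GWAS p-value threshold bin P_T is the sum of squared
z-scores of its mapped SNPs with p < P_T; its null distribution under LD
is a quadratic form in correlated normals approximated by Satterthwaite
moment matching to a scaled chi-square.  Competitive gene-set enrichment
regresses gene z-statistics on set membership with gene-level covariates.
Individual-level pathway polygenic scores (PES) are weighted sums of
LD-pruned (r^2 < 0.1) pathway SNP dosages, standardized to SD units, and
their quintiles are tested against disease with logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GeneStat",
    "map_snps_to_genes",
    "gene_statistic",
    "competitive_enrichment",
    "compute_pes",
    "quintile_association",
]

P_THRESHOLD_BINS = (0.5, 0.05, 0.005)


def map_snps_to_genes(
    gwas: pd.DataFrame,
    annotation: pd.DataFrame,
    *,
    upstream: int = 5_000,
    downstream: int = 1_500,
) -> dict[str, list[str]]:
    """Map SNPs to genes using strand-aware asymmetric windows.

    ``annotation`` is BED-derived (gene, chrom, start, end, strand) with
    1-based inclusive coordinates.  "Upstream" is relative to the
    transcription direction: a plus-strand gene extends ``upstream`` bp
    before its start and ``downstream`` bp past its end; a minus-strand
    gene the mirror image.  A SNP may map to several genes; genes without
    any mapped SNP are omitted.
    """
    out: dict[str, list[str]] = {}
    for _, g in annotation.iterrows():
        if g["strand"] == "+":
            lo, hi = g["start"] - upstream, g["end"] + downstream
        else:
            lo, hi = g["start"] - downstream, g["end"] + upstream
        hit = gwas.loc[
            (gwas["CHR"].astype(str) == str(g["chrom"]))
            & (gwas["POS"] >= lo) & (gwas["POS"] <= hi), "SNP"
        ]
        if len(hit):
            out[g["gene"]] = hit.tolist()
    return out


@dataclass
class GeneStat:
    gene: str
    p_threshold_bin: float
    n_snps: int
    statistic: float  # sum of squared z-scores
    scale_c: float
    df_f: float
    gene_p: float
    gene_z: float


def gene_statistic(
    z: np.ndarray,
    ld: np.ndarray,
    *,
    gene: str = "",
    p_threshold: float = 1.0,
    gwas_p: np.ndarray | None = None,
) -> GeneStat:
    """Sum-of-chi-square gene statistic with a Satterthwaite null.

    With m included SNPs and LD matrix R, the null of ``S = sum z_j^2`` is
    a quadratic form with mean ``E = m`` and variance ``V = 2 sum r_ij^2``;
    matching moments gives scale ``c = V/(2E)`` and df ``f = 2E^2/V``, and
    ``gene_p = P(chi2_f > S/c)``.  ``gene_z`` is the probit transform.
    SNPs with GWAS p >= ``p_threshold`` are excluded before aggregation
    when ``gwas_p`` is supplied; a gene left with no SNPs raises.
    """
    z = np.asarray(z, dtype=float)
    R = np.asarray(ld, dtype=float)
    if gwas_p is not None:
        keep = np.asarray(gwas_p, dtype=float) < p_threshold
        z = z[keep]
        R = R[np.ix_(keep, keep)]
    m = len(z)
    if m == 0:
        raise ValueError(f"gene {gene!r}: no SNPs below the p-value threshold")
    if not np.all(np.isfinite(R)) or R.shape != (m, m):
        raise ValueError("invalid LD matrix")
    s = float(np.sum(z**2))
    e = float(m)
    v = float(2.0 * np.sum(R**2))
    c = v / (2.0 * e)
    f = 2.0 * e**2 / v
    gene_p = float(stats.chi2.sf(s / c, f))
    gene_p = min(max(gene_p, 1e-300), 1.0)
    gene_z = float(stats.norm.isf(gene_p))
    return GeneStat(gene, p_threshold, m, s, c, f, gene_p, gene_z)


def competitive_enrichment(
    gene_stats: pd.DataFrame,
    gene_set: set[str] | list[str],
    *,
    p_threshold_bin: float | None = None,
    pathway: str = "",
) -> pd.Series:
    """Competitive gene-set enrichment: OLS of gene z on set membership.

    ``gene_stats`` has columns gene, gene_z, log_length, log_nsnps.  The
    one-sided p tests whether member genes are *more* associated than
    non-members, adjusting for the gene-level covariates.  Requires at
    least two member genes and at least one non-member.
    """
    members = set(gene_set) & set(gene_stats["gene"])
    if len(members) < 2:
        raise ValueError("gene set has fewer than 2 genes with statistics")
    indicator = gene_stats["gene"].isin(members).to_numpy(float)
    if indicator.all():
        raise ValueError("gene set covers all genes: no contrast")
    X = np.column_stack([
        np.ones(len(gene_stats)), indicator,
        gene_stats["log_length"].to_numpy(float),
        gene_stats["log_nsnps"].to_numpy(float),
    ])
    res = sm.OLS(gene_stats["gene_z"].to_numpy(float), X).fit()
    beta, se = float(res.params[1]), float(res.bse[1])
    tval = beta / se
    one_sided = float(stats.t.sf(tval, res.df_resid))
    return pd.Series({
        "pathway": pathway, "n_genes": len(members), "beta_set": beta,
        "se": se, "one_sided_p": one_sided,
        "p_threshold_bin": p_threshold_bin,
        "significant": one_sided < 1e-3,
    })


def compute_pes(
    dosages: np.ndarray,
    variant_ids: list[str],
    gwas: pd.DataFrame,
    pathway_snps: list[str],
    ld: pd.DataFrame,
    *,
    r2_prune: float = 0.1,
    p_threshold: float = 1.0,
    pathway: str = "",
) -> pd.DataFrame:
    """Individual-level pathway polygenic score, standardized, in quintiles.

    Pathway-mapped SNPs (de-duplicated across overlapping genes) with GWAS
    p < ``p_threshold`` are pruned greedily in ascending-p order (ties by
    position) at r^2 < ``r2_prune``; the raw score is the dosage-weighted
    sum of GWAS betas; the standardized score has mean 0, SD 1 in the
    cohort; quintiles cut at the empirical 20/40/60/80 percentiles.
    """
    from pharmtri.mr import greedy_ld_prune

    snps = sorted(set(pathway_snps))
    cand = gwas.loc[gwas["SNP"].isin(snps) & (gwas["P"] < p_threshold),
                    ["SNP", "POS", "P", "BETA"]].copy()
    if cand.empty:
        raise ValueError(f"pathway {pathway!r}: no SNPs survive the filters")
    kept = greedy_ld_prune(cand, ld, r2_max=r2_prune,
                           sort_by=["P", "POS", "SNP"],
                           ascending=[True, True, True])
    idx = {v: j for j, v in enumerate(variant_ids)}
    cols = [idx[s] for s in kept["SNP"]]
    raw = dosages[:, cols] @ kept["BETA"].to_numpy(float)
    sd = raw.std()
    if sd == 0:
        raise ValueError(f"pathway {pathway!r}: zero-variance score")
    std = (raw - raw.mean()) / sd
    quintile = np.searchsorted(np.quantile(std, [0.2, 0.4, 0.6, 0.8]),
                               std, side="right") + 1
    return pd.DataFrame({
        "individual": np.arange(len(raw)), "pathway": pathway,
        "raw_score": raw, "standardized_score": std, "quintile": quintile,
    })


def quintile_association(
    pes: pd.DataFrame,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
) -> dict:
    """Disease risk across PES quintiles (lowest quintile as reference).

    Logistic regression of the binary outcome on quintile indicators
    (Q2-Q5) plus covariates, and a second model on the continuous per-SD
    score.  Returns per-quintile ORs with 95% CIs and the per-SD estimate.
    A quintile with no cases (or no controls) yields an unbounded CI and
    is flagged.
    """
    y = np.asarray(outcome, dtype=float)
    q = pes["quintile"].to_numpy()
    cov = (np.empty((len(y), 0)) if covariates is None
           else np.asarray(covariates, dtype=float))
    Xq = np.column_stack([np.ones(len(y))]
                         + [(q == k).astype(float) for k in (2, 3, 4, 5)])
    X = np.column_stack([Xq, cov])
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    quintiles = {}
    for i, k in enumerate((2, 3, 4, 5), start=1):
        b, se = float(res.params[i]), float(res.bse[i])
        cases = int(y[q == k].sum())
        controls = int((1 - y[q == k]).sum())
        unbounded = cases == 0 or controls == 0
        quintiles[k] = {
            "or": float(np.exp(b)),
            "ci": (None, None) if unbounded
            else (float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se))),
            "p": float(res.pvalues[i]),
            "unbounded": unbounded,
        }
    Xc = np.column_stack([np.ones(len(y)),
                          pes["standardized_score"].to_numpy(float), cov])
    resc = sm.GLM(y, Xc, family=sm.families.Binomial()).fit()
    return {
        "quintile_or": quintiles,
        "per_sd_beta": float(resc.params[1]),
        "per_sd_se": float(resc.bse[1]),
        "per_sd_p": float(resc.pvalues[1]),
    }
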