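"""Gene-by-medication interaction scans (TxEWAS-style).

Two-step design: genetically predicted expression is imputed from dosages
using externally trained weight tables, then the interaction between
predicted expression and medication exposure is tested in linear (WMH) or
logistic (dementia) regressions with heteroskedasticity-robust sandwich
variance.  Multiplicity across genes and tissues is controlled with the
hierarchical (Benjamini-Bogomolov) FDR, and a significant binary-outcome
interaction is summarized as the fractional attenuation of the medication
main effect per SD of predicted expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "TxewasFit",
    "AttenuationSummary",
    "DEFAULT_COVARIATES",
    "impute_expression",
    "power_screen",
    "fit_interaction",
    "hierarchical_fdr",
    "attenuation",
    "endogeneity_check",
]

#: Covariate columns used by default in the interaction and sensitivity
#: models: age, sex, birth year, deprivation index and 16 genotype PCs.
DEFAULT_COVARIATES = ["age", "sex", "birth_year", "townsend"] + [
    f"pc{i}" for i in range(1, 17)
]


def impute_expression(
    dosages: np.ndarray,
    variant_ids: list[str],
    weights: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Predict expression as a weighted dosage sum, standardized per gene.

    ``weights`` has columns (gene, tissue, variant, weight).  Genes whose
    weight variants have no overlap with the panel, or whose prediction has
    zero variance, are dropped and reported in the returned log list.
    Output columns are ``gene@tissue``.
    """
    idx = {v: j for j, v in enumerate(variant_ids)}
    preds = {}
    dropped: list[str] = []
    for (gene, tissue), sub in weights.groupby(["gene", "tissue"]):
        cols = [idx[v] for v in sub["variant"] if v in idx]
        w = np.array([float(r["weight"]) for _, r in sub.iterrows()
                      if r["variant"] in idx])
        key = f"{gene}@{tissue}"
        if len(cols) == 0:
            dropped.append(f"{key}: no overlapping variants")
            continue
        score = dosages[:, cols] @ w
        sd = score.std()
        if sd == 0:
            dropped.append(f"{key}: zero-variance prediction")
            continue
        preds[key] = (score - score.mean()) / sd
    return pd.DataFrame(preds), dropped


def power_screen(
    pheno: pd.DataFrame,
    atc_class: str,
    *,
    outcome: str = "dementia",
    min_exposed: int = 100,
) -> bool:
    """A drug class is powered iff its exposed count with a non-missing
    outcome reaches ``min_exposed``."""
    sub = pheno.loc[(pheno["atc_class"] == atc_class) & (pheno["drug"] == 1)]
    return int(sub[outcome].notna().sum()) >= min_exposed


@dataclass
class TxewasFit:
    outcome: str
    atc_class: str
    gene: str
    tissue: str
    beta_main_drug: float
    se_main_drug: float
    p_main_drug: float
    beta_expr: float
    beta_interaction: float
    se_interaction: float
    p_interaction: float
    n_exposed: int
    family: str = "gaussian"
    hfdr_q: float | None = None
    caveats: list[str] = field(default_factory=list)


def fit_interaction(
    pheno: pd.DataFrame,
    outcome: str,
    expr_col: str,
    *,
    covariates: list[str] | None = None,
    family: str | None = None,
    gene: str = "",
    tissue: str = "",
    atc_class: str = "",
) -> TxewasFit:
    """Fit ``outcome ~ drug + expr + drug:expr + covariates``.

    Identity link for continuous outcomes, logit for binary; all standard
    errors are heteroskedasticity-robust (HC0 sandwich) and p-values are
    Wald.  A logistic fit exhibiting separation raises ``ValueError`` so
    the caller can exclude and log the fit.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    df = pheno.dropna(subset=[outcome, "drug", expr_col] + covariates)
    drug = df["drug"].to_numpy(dtype=float)
    if drug.std() == 0:
        raise ValueError("drug indicator has zero variance")
    expr = df[expr_col].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(df)), drug, expr, drug * expr, df[covariates].to_numpy(float)]
    )
    y = df[outcome].to_numpy(dtype=float)
    if family is None:
        family = "binomial" if set(np.unique(y)) <= {0.0, 1.0} else "gaussian"
    fam = sm.families.Binomial() if family == "binomial" else sm.families.Gaussian()
    try:
        res = sm.GLM(y, X, family=fam).fit(cov_type="HC0")
    except PerfectSeparationError as err:
        raise ValueError(f"separation in logistic fit: {err}") from err
    if family == "binomial" and (
        not np.all(np.isfinite(res.bse)) or np.max(np.abs(res.params[1:4])) > 15
    ):
        raise ValueError("separation in logistic fit: diverging coefficients")
    return TxewasFit(
        outcome=outcome, atc_class=atc_class, gene=gene, tissue=tissue,
        beta_main_drug=float(res.params[1]), se_main_drug=float(res.bse[1]),
        p_main_drug=float(res.pvalues[1]),
        beta_expr=float(res.params[2]),
        beta_interaction=float(res.params[3]),
        se_interaction=float(res.bse[3]),
        p_interaction=float(res.pvalues[3]),
        n_exposed=int(drug.sum()), family=family,
    )


def _simes(pvals: np.ndarray) -> float:
    p = np.sort(np.asarray(pvals, dtype=float))
    m = len(p)
    return float(min(1.0, (m * p / np.arange(1, m + 1)).min()))


def hierarchical_fdr(
    pvals: pd.DataFrame, q: float = 0.05
) -> pd.DataFrame:
    """Two-stage Benjamini-Bogomolov FDR over tissues nested in genes.

    ``pvals`` has columns (gene, tissue, p).  Stage 1 screens genes with
    BH at level ``q`` applied to per-gene Simes p-values across tissues;
    stage 2 applies BH across tissues *within* each selected gene at the
    adjusted level ``q * R / m`` (R selected genes, m total genes).
    Returns the input with ``gene_selected``, ``selected`` flags and
    ``hfdr_q`` (the within-gene BH-adjusted p scaled by m/R; NaN for
    genes screened out at stage 1).
    """
    if pvals.empty:
        raise ValueError("empty p-value table")
    df = pvals.copy()
    gene_p = df.groupby("gene")["p"].apply(lambda s: _simes(s.to_numpy()))
    reject, _, _, _ = np.array(
        multipletests(gene_p.to_numpy(), alpha=q, method="fdr_bh"), dtype=object
    )
    selected_genes = set(gene_p.index[np.asarray(reject, dtype=bool)])
    m = gene_p.size
    R = len(selected_genes)
    df["gene_selected"] = df["gene"].isin(selected_genes)
    df["hfdr_q"] = np.nan
    df["selected"] = False
    if R > 0:
        level = q * R / m
        for gene in selected_genes:
            mask = df["gene"] == gene
            rej, adj, _, _ = multipletests(
                df.loc[mask, "p"].to_numpy(), alpha=level, method="fdr_bh"
            )
            df.loc[mask, "hfdr_q"] = np.minimum(adj * m / R, 1.0)
            df.loc[mask, "selected"] = rej
    return df


@dataclass
class AttenuationSummary:
    atc_class: str
    gene: str
    outcome: str
    attenuation_fraction: float | None


def attenuation(fit: TxewasFit) -> AttenuationSummary:
    """How much one SD of predicted expression offsets the drug effect.

    Binary outcomes: ``1 - exp(beta_interaction)`` -- the fractional
    reduction of the medication odds ratio per SD of expression.
    Continuous outcomes: ``-beta_interaction / beta_main_drug`` -- the
    fraction of the main effect offset per SD (undefined when the main
    effect is zero, reported as missing).
    """
    if fit.family == "binomial":
        frac = 1.0 - float(np.exp(fit.beta_interaction))
    else:
        if fit.beta_main_drug == 0:
            frac = None
        else:
            frac = -fit.beta_interaction / fit.beta_main_drug
    return AttenuationSummary(fit.atc_class, fit.gene, fit.outcome, frac)


def endogeneity_check(
    pheno: pd.DataFrame,
    expr_cols: list[str],
    *,
    covariates: list[str] | None = None,
    outcomes: tuple[str, ...] = ("drug", "wmh", "dementia"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Main effects of predicted expression on drug use and both outcomes.

    A gene whose expression predicts *treatment* flags endogeneity
    (confounding-by-indication) risk; that flag should be propagated as a
    caveat on the corresponding interaction fits.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    rows = []
    for col in expr_cols:
        for outcome in outcomes:
            df = pheno.dropna(subset=[outcome, col] + covariates)
            y = df[outcome].to_numpy(dtype=float)
            X = np.column_stack(
                [np.ones(len(df)), df[col].to_numpy(float),
                 df[covariates].to_numpy(float)]
            )
            binary = set(np.unique(y)) <= {0.0, 1.0}
            fam = sm.families.Binomial() if binary else sm.families.Gaussian()
            res = sm.GLM(y, X, family=fam).fit(cov_type="HC0")
            rows.append({
                "expr": col, "outcome": outcome,
                "beta": float(res.params[1]), "se": float(res.bse[1]),
                "p": float(res.pvalues[1]),
                "endogeneity_flag": outcome == "drug" and res.pvalues[1] < alpha,
            })
    return pd.DataFrame(rows)
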