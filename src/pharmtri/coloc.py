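"""Colocalization, TWAS, and INTACT-style integration.

The colocalization model enumerates five hypotheses for a region shared by
two traits -- H0 no association, H1/H2 association with one trait only,
H3 two distinct causal variants, H4 one shared causal variant -- scoring
each configuration with per-variant Wakefield ABFs and the standard priors
p1, p2, p12.  PP4 (shared variant) is the gene-level colocalization
probability (GLCP) consumed downstream.

The INTACT-style posterior combines the TWAS z-score with the GLCP: the
GLCP (floored at a truncation t) acts as the prior that the gene is
causal, and the TWAS evidence enters through a Bayes factor averaged over
a grid of prior-variance multipliers K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from pharmtri.finemap import log_abf

__all__ = [
    "ColocResult",
    "IntactResult",
    "coloc_abf",
    "twas_z",
    "intact_posterior",
    "prioritize_pcts",
]

DEFAULT_K_GRID = (1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4, sums to 1
    priors: tuple[float, float, float]  # p1, p2, p12
    log_abf1: np.ndarray
    log_abf2: np.ndarray
    snps: list[str] = field(default_factory=list)

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def as_series(self) -> pd.Series:
        return pd.Series(self.pp, index=[f"pp{i}" for i in range(5)])


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when equal."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.15,
    *,
    harmonized: bool = True,
) -> ColocResult:
    """Enumeration colocalization from two summary-statistic frames.

    Both frames carry SNP, BETA, SE for the *same* harmonized variants.
    ``prior_sd1``/``prior_sd2`` are the Wakefield effect-size prior SDs for
    each trait (0.15 suits molecular traits and SD-scaled quantitative
    traits).  Returns posterior probabilities PP0..PP4.
    """
    if not harmonized:
        raise ValueError("harmonize inputs before colocalization")
    merged = stats1.merge(stats2, on="SNP", suffixes=("_1", "_2"))
    if merged.empty:
        raise ValueError("no overlapping variants between the two traits")
    l1 = np.atleast_1d(log_abf(merged["BETA_1"].to_numpy(),
                               merged["SE_1"].to_numpy(), prior_sd1))
    l2 = np.atleast_1d(log_abf(merged["BETA_2"].to_numpy(),
                               merged["SE_2"].to_numpy(), prior_sd2))
    lse1 = logsumexp(l1)
    lse2 = logsumexp(l2)
    lse12 = logsumexp(l1 + l2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + lse1
    lh[2] = np.log(p2) + lse2
    # H3: distinct causal variants i != j
    lh[3] = np.log(p1) + np.log(p2) + _logdiffexp(lse1 + lse2, lse12)
    lh[4] = np.log(p12) + lse12
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(pp, (p1, p2, p12), l1, l2, merged["SNP"].tolist())


def twas_z(
    weights: np.ndarray, gwas_z: np.ndarray, ld: np.ndarray
) -> float:
    """TWAS association z-score: ``w'z / sqrt(w'Rw)``.

    ``weights`` are eQTL effect weights, ``gwas_z`` the GWAS z-scores at
    the same (allele-aligned) variants, and ``ld`` their correlation
    matrix.  Raises if the weighted variance ``w'Rw`` is not positive.
    """
    w = np.asarray(weights, dtype=float)
    z = np.asarray(gwas_z, dtype=float)
    denom = float(w @ np.asarray(ld, dtype=float) @ w)
    if denom <= 0:
        raise ValueError(f"weight variance w'Rw = {denom:.3g} is not positive")
    return float(w @ z / np.sqrt(denom))


@dataclass
class IntactResult:
    gene: str
    tissue: str
    twas_z: float
    glcp: float
    prior: float
    log_bf: float
    posterior: float
    k_grid: tuple[float, ...] = DEFAULT_K_GRID

    @property
    def bayes_factor(self) -> float:
        return float(np.exp(self.log_bf))


def _log_bf_kgrid(z: float, k_grid: tuple[float, ...]) -> float:
    """log of the K-grid-averaged Bayes factor for a z-score."""
    ks = np.asarray(k_grid, dtype=float)
    terms = -0.5 * np.log1p(ks) + z**2 * ks / (2.0 * (1.0 + ks))
    return float(logsumexp(terms) - np.log(len(ks)))


def intact_posterior(
    twas_z: float,
    glcp: float,
    prior_fun: str = "linear",
    truncation_t: float = 0.05,
    k_grid: tuple[float, ...] = DEFAULT_K_GRID,
    *,
    gene: str = "",
    tissue: str = "",
) -> IntactResult:
    """Posterior probability that a gene causally mediates the trait.

    The colocalization probability (floored at ``truncation_t`` for the
    ``linear`` prior; passed through a logistic for ``expit``; thresholded
    at 0.5 for ``step``) serves as the prior pi; the TWAS z-score supplies
    the Bayes factor BF averaged over the K grid; and

        posterior = pi * BF / (pi * BF + 1 - pi).
    """
    if not (0.0 <= glcp <= 1.0):
        raise ValueError(f"glcp must lie in [0, 1], got {glcp}")
    if prior_fun == "linear":
        pi = max(glcp, truncation_t)
    elif prior_fun == "expit":
        pi = max(float(1.0 / (1.0 + np.exp(-10.0 * (glcp - 0.5)))), truncation_t)
    elif prior_fun == "step":
        pi = truncation_t if glcp < 0.5 else 1.0 - truncation_t
    else:
        raise ValueError(f"unknown prior_fun {prior_fun!r}")
    lbf = _log_bf_kgrid(float(twas_z), k_grid)
    if pi >= 1.0:
        post = 1.0
    else:
        log_odds = np.log(pi) - np.log1p(-pi) + lbf
        post = float(1.0 / (1.0 + np.exp(-log_odds)))
    return IntactResult(gene, tissue, float(twas_z), float(glcp), float(pi),
                        lbf, post, tuple(k_grid))


def prioritize_pcts(
    results: list[IntactResult], threshold: float = 0.90
) -> pd.DataFrame:
    """Genes whose INTACT posterior strictly exceeds the threshold.

    A gene qualifies if it passes in at least one tissue; the qualifying
    tissues are listed.  Output is ordered by best posterior descending,
    then gene id, for determinism.  An empty result is a valid outcome.
    """
    rows = []
    by_gene: dict[str, list[IntactResult]] = {}
    for r in results:
        by_gene.setdefault(r.gene, []).append(r)
    for gene, rs in by_gene.items():
        passing = [r for r in rs if r.posterior > threshold]
        if passing:
            best = max(r.posterior for r in passing)
            tissues = sorted({r.tissue for r in passing})
            rows.append({"gene": gene, "best_posterior": best,
                         "tissues": ",".join(tissues),
                         "n_tissues": len(tissues)})
    out = pd.DataFrame(rows, columns=["gene", "best_posterior", "tissues", "n_tissues"])
    if not out.empty:
        out = out.sort_values(
            ["best_posterior", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    return out
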