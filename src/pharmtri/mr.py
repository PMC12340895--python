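"""Mendelian randomization suite with triangulation.

Instrument construction (fine-mapped eQTLs, thresholded pQTLs, single-cell
eQTLs, all LD-pruned at r^2 < 0.1), causal-effect estimators (Wald ratio,
fixed-effect IVW, MR-Egger, weighted median, and a simplified robust
profile score), fixed-effect meta-analysis of study-level estimates, the
triangulation decision rule (IVW plus at least two concordant
pleiotropy-robust methods plus colocalization PP4 >= 0.75), and a
kinship-aware linear mixed model for observational protein-phenotype
validation.

All causal estimates are expressed per 1 SD of the exposure; instruments
are oriented so the effect allele increases the exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MrEstimate",
    "orient_instruments",
    "greedy_ld_prune",
    "select_instruments_eqtl",
    "select_instruments_pqtl",
    "select_instruments_sc",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "raps_simplified",
    "fixed_effect_meta",
    "triangulate",
    "kinship_lmm",
]

INSTRUMENT_COLUMNS = ["SNP", "exposure_beta", "exposure_se",
                      "outcome_beta", "outcome_se"]

_METHOD_MINIMUM = {"wald": 1, "ivw": 2, "egger": 3,
                   "weighted_median": 3, "raps_simplified": 3}


@dataclass
class MrEstimate:
    """A method-tagged causal-effect estimate (per exposure SD)."""

    method: str
    beta: float
    se: float
    p: float
    n_instruments: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.isf((1 - level) / 2)
        return self.beta - z * self.se, self.beta + z * self.se


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0


def orient_instruments(inst: pd.DataFrame) -> pd.DataFrame:
    """Flip alleles so every exposure beta is positive.

    The outcome beta flips with the exposure beta, leaving the ratio (and
    every estimator built on it) unchanged.
    """
    out = inst.copy()
    flip = out["exposure_beta"] < 0
    for col in ("exposure_beta", "outcome_beta"):
        out.loc[flip, col] = -out.loc[flip, col]
    return out


def greedy_ld_prune(
    candidates: pd.DataFrame,
    ld: pd.DataFrame,
    *,
    r2_max: float = 0.1,
    sort_by: list[str],
    ascending: list[bool],
) -> pd.DataFrame:
    """Greedy selection: walk candidates in priority order, keep a variant
    only if its r^2 with every already-kept variant is below ``r2_max``.

    ``ld`` is a SNP-indexed correlation (r) matrix covering all candidates.
    Ties in the primary key are broken by the remaining sort keys (the
    callers append position and SNP id for determinism).
    """
    order = candidates.sort_values(sort_by, ascending=ascending, kind="mergesort")
    kept: list[str] = []
    for snp in order["SNP"]:
        r = ld.loc[snp, kept] if kept else []
        if kept and float(np.max(np.asarray(r) ** 2)) >= r2_max:
            continue
        kept.append(snp)
    return order.loc[order["SNP"].isin(kept)].reset_index(drop=True)


def select_instruments_eqtl(
    fine_variants: pd.DataFrame,
    ld: pd.DataFrame,
    *,
    pip_min: float = 0.1,
    r2_max: float = 0.1,
) -> pd.DataFrame:
    """Instruments from fine-mapped eQTLs: PIP-ranked greedy r^2 pruning.

    ``fine_variants`` carries SNP, POS, pip plus the exposure/outcome
    columns.  Candidates below ``pip_min`` are discarded first.  Returns an
    empty frame (gene skipped by the caller) when nothing qualifies.
    """
    cand = fine_variants.loc[fine_variants["pip"] >= pip_min].copy()
    if cand.empty:
        return cand
    return greedy_ld_prune(cand, ld, r2_max=r2_max,
                           sort_by=["pip", "POS", "SNP"],
                           ascending=[False, True, True])


def select_instruments_pqtl(
    pqtl: pd.DataFrame,
    tss: int,
    ld: pd.DataFrame,
    *,
    p_max: float = 1e-3,
    tss_window: int = 1_000_000,
    r2_max: float = 0.1,
) -> pd.DataFrame:
    """pQTL instruments: P < p_max (strict), within 1 Mb of the TSS
    (inclusive), then greedy r^2 pruning by ascending p."""
    cand = pqtl.loc[
        (pqtl["P"] < p_max) & ((pqtl["POS"] - tss).abs() <= tss_window)
    ].copy()
    if cand.empty:
        return cand
    return greedy_ld_prune(cand, ld, r2_max=r2_max,
                           sort_by=["P", "POS", "SNP"],
                           ascending=[True, True, True])


def select_instruments_sc(
    sc_eqtl: pd.DataFrame,
    ld: pd.DataFrame,
    *,
    p_max: float = 1e-5,
    r2_max: float = 0.1,
) -> pd.DataFrame:
    """Single-cell eQTL instruments: P < 1e-5 (strict) then r^2 pruning."""
    cand = sc_eqtl.loc[sc_eqtl["P"] < p_max].copy()
    if cand.empty:
        return cand
    return greedy_ld_prune(cand, ld, r2_max=r2_max,
                           sort_by=["P", "POS", "SNP"],
                           ascending=[True, True, True])


def _require(inst: pd.DataFrame, method: str) -> pd.DataFrame:
    n = len(inst)
    need = _METHOD_MINIMUM[method]
    if n < need:
        raise ValueError(f"{method} requires >= {need} instruments, got {n}")
    return orient_instruments(inst)


def _ratios(inst: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument Wald ratios and first-order delta-method SEs."""
    bx = inst["exposure_beta"].to_numpy(dtype=float)
    sx = inst["exposure_se"].to_numpy(dtype=float)
    by = inst["outcome_beta"].to_numpy(dtype=float)
    sy = inst["outcome_se"].to_numpy(dtype=float)
    if np.any(bx == 0):
        raise ValueError("exposure beta of zero: Wald ratio undefined")
    ratio = by / bx
    se = np.sqrt(sy**2 + ratio**2 * sx**2) / np.abs(bx)
    return ratio, se


def wald_ratio(inst: pd.DataFrame) -> MrEstimate:
    """Single-instrument causal estimate: outcome beta / exposure beta."""
    inst = _require(inst, "wald")
    if len(inst) != 1:
        raise ValueError(f"wald_ratio takes exactly one instrument, got {len(inst)}")
    ratio, se = _ratios(inst)
    return MrEstimate("wald", float(ratio[0]), float(se[0]),
                      _normal_p(float(ratio[0]), float(se[0])), 1)


def ivw(inst: pd.DataFrame) -> MrEstimate:
    """Fixed-effect inverse-variance weighting of per-instrument ratios."""
    inst = _require(inst, "ivw")
    ratio, se = _ratios(inst)
    w = 1.0 / se**2
    beta = float(np.sum(w * ratio) / np.sum(w))
    se_ivw = float(1.0 / np.sqrt(np.sum(w)))
    return MrEstimate("ivw", beta, se_ivw, _normal_p(beta, se_ivw), len(inst))


def mr_egger(inst: pd.DataFrame) -> MrEstimate:
    """Weighted regression of outcome on exposure betas with an intercept.

    Weights 1/outcome_se^2; the slope is the causal estimate and the
    intercept the average directional pleiotropy.  SEs carry the standard
    multiplicative random-effects scale max(1, residual MSE) so that
    balanced pleiotropy widens rather than invalidates the intervals.
    """
    inst = _require(inst, "egger")
    bx = inst["exposure_beta"].to_numpy(dtype=float)
    by = inst["outcome_beta"].to_numpy(dtype=float)
    w = 1.0 / inst["outcome_se"].to_numpy(dtype=float) ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    dof = len(bx) - 2
    scale = max(1.0, float(np.sum(w * resid**2) / dof)) if dof > 0 else 1.0
    cov = scale * np.linalg.inv(xtwx)
    slope, slope_se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    icpt, icpt_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
    return MrEstimate("egger", slope, slope_se, _normal_p(slope, slope_se),
                      len(inst), egger_intercept=icpt, egger_intercept_se=icpt_se)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (cumulative weights centered per value)."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(v[0])
    if cum[-1] <= 0.5:
        return float(v[-1])
    return float(np.interp(0.5, cum, v))


def weighted_median(
    inst: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted median of Wald ratios; robust to <50% invalid weight.

    SE by parametric bootstrap: exposure and outcome betas are re-drawn
    from normals centered at the observed values with the reported SEs,
    and the weighted median recomputed (seeded for reproducibility).
    """
    inst = _require(inst, "weighted_median")
    ratio, se = _ratios(inst)
    w = 1.0 / se**2
    beta = _weighted_median(ratio, w)
    rng = np.random.default_rng(seed)
    bx = inst["exposure_beta"].to_numpy(dtype=float)
    sx = inst["exposure_se"].to_numpy(dtype=float)
    by = inst["outcome_beta"].to_numpy(dtype=float)
    sy = inst["outcome_se"].to_numpy(dtype=float)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.standard_normal(len(bx))
        bys = by + sy * rng.standard_normal(len(by))
        bxs[bxs == 0] = 1e-12
        r = bys / bxs
        s = np.sqrt(sy**2 + r**2 * sx**2) / np.abs(bxs)
        boots[b] = _weighted_median(r, 1.0 / s**2)
    se_b = float(boots.std(ddof=1))
    return MrEstimate("weighted_median", float(beta), se_b,
                      _normal_p(float(beta), se_b), len(inst))


def _huber_psi(t: np.ndarray, k: float) -> np.ndarray:
    return np.clip(t, -k, k)


def raps_simplified(
    inst: pd.DataFrame, huber_k: float = 1.345,
    bracket: tuple[float, float] = (-10.0, 10.0),
) -> MrEstimate:
    """Robust profile-score estimator (no overdispersion parameter).

    Solves ``sum_j gamma_j * psi(t_j(beta)) = 0`` with the Huber psi and
    standardized profile residuals
    ``t_j = (Gamma_j - beta*gamma_j) / sqrt(se_Gamma_j^2 + beta^2 se_gamma_j^2)``.
    The root is located by a sign-change scan over a bracketed grid and
    refined with Brent's method; the SE comes from the sandwich formula
    with E[psi^2] under a standard-normal residual and a numerical
    derivative of the estimating function.
    """
    inst = _require(inst, "raps_simplified")
    gx = inst["exposure_beta"].to_numpy(dtype=float)
    sx = inst["exposure_se"].to_numpy(dtype=float)
    gy = inst["outcome_beta"].to_numpy(dtype=float)
    sy = inst["outcome_se"].to_numpy(dtype=float)

    def estfun(beta: float) -> float:
        s = np.sqrt(sy**2 + beta**2 * sx**2)
        t = (gy - beta * gx) / s
        return float(np.sum(gx * _huber_psi(t, huber_k)))

    grid = np.linspace(bracket[0], bracket[1], 201)
    vals = np.array([estfun(b) for b in grid])
    sign_change = np.where(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise RuntimeError("raps_simplified: no sign change of the estimating "
                           "function over the bracket; non-convergence")
    i = sign_change[0]
    beta = float(optimize.brentq(estfun, grid[i], grid[i + 1], xtol=1e-10))

    # sandwich variance: Var(U) with E psi^2 for a Huber psi, |dU/dbeta|
    k = huber_k
    e_psi2 = (
        stats.norm.cdf(k) - stats.norm.cdf(-k)
        - 2 * k * stats.norm.pdf(k)
        + 2 * k**2 * stats.norm.sf(k)
    )
    var_u = float(np.sum(gx**2) * e_psi2)
    h = 1e-5 * max(1.0, abs(beta))
    dU = (estfun(beta + h) - estfun(beta - h)) / (2 * h)
    se = float(np.sqrt(var_u) / abs(dU))
    return MrEstimate("raps_simplified", beta, se, _normal_p(beta, se), len(inst))


def fixed_effect_meta(
    estimates: list[tuple[float, float]]
) -> tuple[float, float, float]:
    """Inverse-variance fixed-effect meta-analysis of (beta, se) pairs."""
    if not estimates:
        raise ValueError("fixed_effect_meta needs at least one estimate")
    betas = np.array([b for b, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return beta, se, _normal_p(beta, se)


@dataclass
class TriangulationVerdict:
    verdict: str  # supported | not_supported | insufficient
    reasons: list[str]


def triangulate(
    estimates: dict[str, MrEstimate],
    pp4: float,
    alpha: float = 0.05,
    *,
    robust_methods: tuple[str, ...] = ("egger", "weighted_median", "raps_simplified"),
    pp4_min: float = 0.75,
) -> TriangulationVerdict:
    """Decision rule: supported iff the IVW estimate is significant, at
    least two pleiotropy-robust methods are significant with the same sign
    as IVW, and colocalization PP4 >= 0.75.

    ``alpha`` defaults to 0.05 and is typically Bonferroni-divided by the
    number of proteins/genes tested by the caller.
    """
    if "ivw" not in estimates:
        return TriangulationVerdict("insufficient", ["missing ivw"])
    available = [m for m in robust_methods if m in estimates]
    if len(available) < 2:
        return TriangulationVerdict(
            "insufficient", ["fewer than two robust methods available"])
    reasons = []
    ivw_est = estimates["ivw"]
    if ivw_est.p >= alpha:
        reasons.append("ivw not significant")
    sign = np.sign(ivw_est.beta)
    concordant = [
        m for m in available
        if estimates[m].p < alpha and np.sign(estimates[m].beta) == sign
    ]
    if len(concordant) < 2:
        reasons.append("fewer than two concordant robust methods")
    if not (pp4 >= pp4_min):
        reasons.append("coloc")
    if reasons:
        return TriangulationVerdict("not_supported", reasons)
    return TriangulationVerdict("supported", [])


def kinship_lmm(
    y: np.ndarray,
    X: np.ndarray,
    kinship: np.ndarray,
    *,
    coef_index: int = 1,
    return_variance: bool = False,
):
    """REML fit of ``y = X b + g + e`` with ``cov(g) = sigma_g^2 * K``.

    ``K`` is the (already doubled, i.e. 2*Phi) kinship matrix and must be
    positive semi-definite.  The model is rotated by K's eigenvectors so
    the covariance is diagonal in ``delta = sigma_g^2 / sigma_e^2``; the
    REML criterion is profiled over ``delta`` with a scalar optimizer.
    Returns (beta, se, p) for the fixed-effect column ``coef_index``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    K = np.asarray(kinship, dtype=float)
    n, p = X.shape
    evals, evecs = np.linalg.eigh(K)
    if evals.min() < -1e-8 * max(1.0, evals.max()):
        raise ValueError("kinship matrix is not positive semi-definite")
    evals = np.clip(evals, 0.0, None)
    yt = evecs.T @ y
    Xt = evecs.T @ X

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        d = delta * evals + 1.0
        Xw = Xt / d[:, None]
        xtx = Xt.T @ Xw
        beta = np.linalg.solve(xtx, Xw.T @ yt)
        r = yt - Xt @ beta
        rss = float(np.sum(r**2 / d))
        sigma2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(sigma2)
            + np.sum(np.log(d))
            + np.linalg.slogdet(xtx)[1]
            + (n - p)
        )
        return -ll

    res = optimize.minimize_scalar(neg_reml, bounds=(-10.0, 10.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    # compare against the no-genetic-variance boundary
    delta = float(np.exp(res.x))
    if neg_reml(-30.0) <= res.fun:
        delta = 0.0
    d = delta * evals + 1.0
    Xw = Xt / d[:, None]
    xtx = Xt.T @ Xw
    beta = np.linalg.solve(xtx, Xw.T @ yt)
    r = yt - Xt @ beta
    sigma2 = float(np.sum(r**2 / d)) / (n - p)
    cov = sigma2 * np.linalg.inv(xtx)
    b = float(beta[coef_index])
    se = float(np.sqrt(cov[coef_index, coef_index]))
    if return_variance:
        sigma_g2 = delta * sigma2
        return b, se, _normal_p(b, se), sigma_g2, sigma2
    return b, se, _normal_p(b, se)
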