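"""Synthetic cohort generator with a complete truth ledger.

Every downstream stage of the pipeline is exercised on data produced here:
LD-blocked genotype dosages, cis-regulated expression and protein levels,
trait and disease GWAS summary statistics, an EHR-style phenotype table with
medication exposure, and paired negative-binomial RNA-seq counts.  All
nonzero simulated effects are recorded in a :class:`TruthLedger` so recovery
by any stage can be scored without re-deriving the simulation.

LD model
--------
Within a block, haplotype alleles follow a copy process: allele ``j`` equals
allele ``j-1`` with probability ``rho`` and is otherwise a fresh
Bernoulli(MAF) draw.  The allele frequency is constant within a block, the
dosage correlation between variants ``i`` and ``j`` is exactly
``rho**|i-j|``, marginals are Hardy-Weinberg, and the implied LD matrix is
positive semi-definite by construction.  Blocks are mutually independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "LdBlockSpec",
    "GeneModel",
    "TruthLedger",
    "Genotypes",
    "EhrCohort",
    "child_rng",
    "simulate_genotypes",
    "simulate_molecular_traits",
    "simulate_gwas",
    "simulate_ehr_cohort",
    "simulate_paired_counts",
    "genomic_inflation",
    "marginal_ols_scan",
    "marginal_logistic_scan",
]

# Fixed per-stream offsets so one root seed drives all generators
# reproducibly; logged to the run manifest by the io layer.
STREAM_OFFSETS = {
    "genotypes": 11,
    "expression": 23,
    "gwas": 37,
    "ehr": 53,
    "counts": 71,
    "misc": 97,
}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Derive a per-stream generator from a single root seed."""
    return np.random.default_rng((int(seed), STREAM_OFFSETS[stream]))


@dataclass(frozen=True)
class LdBlockSpec:
    """Layout of LD-blocked variants.

    Parameters
    ----------
    n_variants : total number of variants.
    block_size : variants per independent LD block.
    rho : correlation between adjacent variants within a block, in [0, 1).
    maf_range : minor allele frequency range, both ends in (0.05, 0.5];
        one frequency is drawn per block.
    """

    n_variants: int
    block_size: int
    rho: float
    maf_range: tuple[float, float] = (0.1, 0.5)

    def __post_init__(self) -> None:
        if self.n_variants < 1 or self.block_size < 1:
            raise ValueError("n_variants and block_size must be positive")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        lo, hi = self.maf_range
        if not (0.05 < lo <= hi <= 0.5):
            raise ValueError(
                f"maf_range must satisfy 0.05 < lo <= hi <= 0.5, got {self.maf_range}"
            )

    @property
    def n_blocks(self) -> int:
        return -(-self.n_variants // self.block_size)

    def block_of(self, j: int) -> int:
        return j // self.block_size

    def ld_matrix(self) -> np.ndarray:
        """Theoretical LD (correlation) matrix: AR(1) within blocks."""
        m = self.n_variants
        idx = np.arange(m)
        r = np.where(
            np.equal.outer(idx // self.block_size, idx // self.block_size),
            self.rho ** np.abs(np.subtract.outer(idx, idx)).astype(float),
            0.0,
        )
        return r


@dataclass(frozen=True)
class GeneModel:
    """A gene with its genomic footprint and cis window."""

    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "+"
    cis_radius: int = 500_000

    def cis_window(self) -> tuple[int, int]:
        return max(1, self.start - self.cis_radius), self.end + self.cis_radius


@dataclass
class TruthLedger:
    """Record of every nonzero simulated effect.

    The ledger is the single source for scoring recovery downstream: causal
    eQTL variants and their effects (SD of expression per allele), mediation
    effects (trait SD per expression SD), direct variant-trait effects
    (horizontal pleiotropy), expression-by-drug interaction effects, paired
    negative-binomial log2 fold changes, and pathway membership.
    """

    causal_variants: dict[str, list[str]] = field(default_factory=dict)
    eqtl_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    mediation_effects: dict[str, float] = field(default_factory=dict)
    direct_trait_effects: dict[str, float] = field(default_factory=dict)
    interaction_effects: dict[str, float] = field(default_factory=dict)
    nb_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    pathway_membership: dict[str, list[str]] = field(default_factory=dict)

    def record_eqtl(self, gene: str, variant: str, beta: float) -> None:
        if beta != 0.0:
            self.causal_variants.setdefault(gene, []).append(variant)
            self.eqtl_effects.setdefault(gene, {})[variant] = float(beta)

    def mediating_genes(self) -> list[str]:
        return sorted(g for g, b in self.mediation_effects.items() if b != 0.0)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        return cls(**json.loads(text))


@dataclass
class Genotypes:
    """Dosage matrix with its variant metadata and theoretical LD."""

    dosages: np.ndarray  # n_individuals x n_variants, values in {0,1,2}
    ld: np.ndarray  # n_variants x n_variants correlation matrix
    maf: np.ndarray
    variant_ids: list[str]
    positions: np.ndarray  # 1-based
    chrom: str = "1"

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def index_of(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)


def _simulate_haplotypes(
    rng: np.random.Generator, n: int, m: int, maf: float, rho: float
) -> np.ndarray:
    """n x m allele matrix for one block via the copy process."""
    alleles = np.empty((n, m), dtype=np.int8)
    fresh = rng.random((n, m)) < maf
    alleles[:, 0] = fresh[:, 0]
    if m > 1:
        copy = rng.random((n, m - 1)) < rho
        for j in range(1, m):
            alleles[:, j] = np.where(copy[:, j - 1], alleles[:, j - 1], fresh[:, j])
    return alleles


def simulate_genotypes(
    spec: LdBlockSpec,
    n_individuals: int,
    seed: int,
    *,
    chrom: str = "1",
    spacing: int = 1_000,
    start_pos: int = 1_000,
) -> Genotypes:
    """Simulate diploid dosages under the block AR(1) haplotype copy model.

    Deterministic given ``seed``; dosages lie in {0, 1, 2}; the empirical
    correlation of adjacent within-block dosages converges to ``spec.rho``.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    rng = child_rng(seed, "genotypes")
    m = spec.n_variants
    dos = np.empty((n_individuals, m), dtype=np.float64)
    mafs = np.empty(m)
    for b in range(spec.n_blocks):
        j0 = b * spec.block_size
        j1 = min(j0 + spec.block_size, m)
        maf = rng.uniform(*spec.maf_range)
        h1 = _simulate_haplotypes(rng, n_individuals, j1 - j0, maf, spec.rho)
        h2 = _simulate_haplotypes(rng, n_individuals, j1 - j0, maf, spec.rho)
        dos[:, j0:j1] = h1 + h2
        mafs[j0:j1] = maf
    positions = start_pos + spacing * np.arange(m)
    ids = [f"rs{i + 1}" for i in range(m)]
    return Genotypes(dos, spec.ld_matrix(), mafs, ids, positions, chrom)


def simulate_molecular_traits(
    geno: Genotypes,
    genes: list[GeneModel],
    truth: TruthLedger,
    noise_sd: float | None = None,
    seed: int = 0,
    *,
    protein_noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate expression and protein matrices from causal cis-eQTLs.

    Expression for gene *g* is ``sum_v beta_v * dosage_v + e`` over the
    ledger's causal variants for *g* (all of which must lie inside the
    gene's cis window).  When ``noise_sd`` is None the residual SD is chosen
    so total expression variance is ~1, making ``beta`` a per-allele effect
    in expression-SD units.  The protein channel shares the genetic
    component and adds independent noise, so pQTL and eQTL signals share
    causal variants by construction.
    """
    rng = child_rng(seed, "expression")
    n = geno.n_individuals
    expr = {}
    prot = {}
    pos_of = dict(zip(geno.variant_ids, geno.positions))
    for gm in genes:
        lo, hi = gm.cis_window()
        g = np.zeros(n)
        for vid, beta in truth.eqtl_effects.get(gm.gene, {}).items():
            p = pos_of.get(vid)
            if p is None or not (lo <= p <= hi):
                raise ValueError(
                    f"causal variant {vid} of {gm.gene} outside cis window [{lo}, {hi}]"
                )
            g = g + beta * geno.dosages[:, geno.index_of(vid)]
        var_g = float(np.var(g))
        if noise_sd is None:
            if var_g >= 1.0:
                raise ValueError(
                    f"genetic variance of {gm.gene} is {var_g:.3f} >= 1; "
                    "cannot standardize to unit total variance"
                )
            sd_e = float(np.sqrt(1.0 - var_g))
        else:
            sd_e = float(noise_sd)
        expr[gm.gene] = g + sd_e * rng.standard_normal(n)
        prot[gm.gene] = g + protein_noise_sd * rng.standard_normal(n)
    return pd.DataFrame(expr), pd.DataFrame(prot)


def marginal_ols_scan(dosages: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Vectorized per-variant simple linear regression of y on dosage."""
    n = len(y)
    x = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    sxx = (x**2).sum(axis=0)
    sxy = x.T @ yc
    beta = sxy / sxx
    rss = (yc**2).sum() - beta * sxy
    se = np.sqrt(rss / (n - 2) / sxx)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return pd.DataFrame({"BETA": beta, "SE": se, "P": np.clip(p, 1e-300, 1.0)})


def marginal_logistic_scan(
    dosages: np.ndarray, y: np.ndarray, max_iter: int = 25, tol: float = 1e-8
) -> pd.DataFrame:
    """Vectorized per-variant logistic regression (intercept + dosage).

    Newton-Raphson run in parallel across variants; each iteration solves
    the per-variant 2x2 system in closed form.
    """
    n, m = dosages.shape
    x = dosages
    b0 = np.full(m, logit(np.clip(y.mean(), 1e-6, 1 - 1e-6)))
    b1 = np.zeros(m)
    for _ in range(max_iter):
        eta = b0 + x * b1[None, :]
        mu = expit(eta)
        w = mu * (1 - mu)
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (x * r).sum(axis=0)
        a = w.sum(axis=0)
        b = (w * x).sum(axis=0)
        d = (w * x * x).sum(axis=0)
        det = a * d - b * b
        step0 = (d * g0 - b * g1) / det
        step1 = (a * g1 - b * g0) / det
        b0 += step0
        b1 += step1
        if max(np.abs(step0).max(), np.abs(step1).max()) < tol:
            break
    eta = b0 + x * b1[None, :]
    mu = expit(eta)
    w = mu * (1 - mu)
    a = w.sum(axis=0)
    b = (w * x).sum(axis=0)
    d = (w * x * x).sum(axis=0)
    det = a * d - b * b
    se = np.sqrt(a / det)
    z = b1 / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"BETA": b1, "SE": se, "P": np.clip(p, 1e-300, 1.0)})


def _summary_frame(geno: Genotypes, scan: pd.DataFrame, n: int) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "SNP": geno.variant_ids,
            "CHR": geno.chrom,
            "POS": geno.positions,
            "EA": "A",
            "OA": "G",
            "EAF": geno.dosages.mean(axis=0) / 2.0,
            "BETA": scan["BETA"].to_numpy(),
            "SE": scan["SE"].to_numpy(),
            "P": scan["P"].to_numpy(),
            "N": n,
        }
    )
    return out


def simulate_gwas(
    geno: Genotypes,
    expression: pd.DataFrame | None,
    truth: TruthLedger,
    seed: int = 0,
    *,
    trait_noise_sd: float | None = None,
    disease_prevalence: float = 0.2,
    liability_scale: float = 1.0,
    disease_model: str = "logistic",
    scan_disease: bool = True,
) -> dict[str, pd.DataFrame]:
    """Simulate a quantitative trait and binary disease, then GWAS both.

    The trait is ``sum_g mediation_g * expression_g + sum_v direct_v *
    dosage_v + e``; the disease arises from the same genetic liability
    through a logistic link (default) or a liability-threshold model.
    Returns summary-statistic frames in the standard schema
    (SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N) keyed by ``"trait"`` and,
    when scanned, ``"disease"``, plus the phenotype vectors under
    ``"phenotypes"``.
    """
    if disease_model not in ("logistic", "liability"):
        raise ValueError(f"unknown disease_model {disease_model!r}")
    rng = child_rng(seed, "gwas")
    n = geno.n_individuals
    liability = np.zeros(n)
    for gene, eff in truth.mediation_effects.items():
        if eff != 0.0:
            liability = liability + eff * expression[gene].to_numpy()
    for vid, eff in truth.direct_trait_effects.items():
        if eff != 0.0:
            liability = liability + eff * geno.dosages[:, geno.index_of(vid)]
    var_g = float(np.var(liability))
    if trait_noise_sd is None:
        trait_noise_sd = float(np.sqrt(max(1.0 - var_g, 0.05)))
    y = liability + trait_noise_sd * rng.standard_normal(n)
    scan = marginal_ols_scan(geno.dosages, y)
    out: dict[str, pd.DataFrame] = {"trait": _summary_frame(geno, scan, n)}

    std_liab = (liability - liability.mean()) / (liability.std() or 1.0)
    if disease_model == "logistic":
        eta = logit(disease_prevalence) + liability_scale * std_liab
        disease = (rng.random(n) < expit(eta)).astype(float)
    else:  # liability threshold
        full = std_liab * liability_scale + rng.standard_normal(n)
        thr = np.quantile(full, 1.0 - disease_prevalence)
        disease = (full > thr).astype(float)
    if scan_disease:
        dscan = marginal_logistic_scan(geno.dosages, disease)
        out["disease"] = _summary_frame(geno, dscan, n)
    out["phenotypes"] = pd.DataFrame({"trait": y, "disease": disease})
    return out


def genomic_inflation(pvals: np.ndarray) -> float:
    """Genomic inflation factor: median chi2 over its null median (0.4549)."""
    chi2 = stats.chi2.isf(np.asarray(pvals, dtype=float), df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


@dataclass
class EhrCohort:
    """Phenotype table for the gene-by-medication arm, plus power flags."""

    table: pd.DataFrame
    n_exposed: int
    powered: bool
    atc_class: str = "N06AX"


def simulate_ehr_cohort(
    geno: Genotypes,
    expr_weights: pd.DataFrame,
    truth: TruthLedger,
    seed: int = 0,
    *,
    drug_prevalence: float = 0.3,
    drug_main_wmh: float = 0.3,
    drug_main_dementia: float = np.log(3.0),
    dementia_prevalence: float = 0.2,
    confounding_by_indication: float = 0.0,
    covariate_scale: float = 0.05,
    min_exposed: int = 100,
    atc_class: str = "N06AX",
) -> EhrCohort:
    """Simulate an EHR-style cohort with drug exposure and two outcomes.

    ``expr_weights`` has columns (gene, variant, weight): the genetically
    predicted expression used in the outcome model, standardized per gene.
    Interaction effects come from the ledger (per SD predicted expression,
    per drug exposure) and apply to both the continuous WMH outcome and the
    log-odds of dementia.  ``confounding_by_indication > 0`` makes drug
    assignment depend on the latent dementia risk, emulating channelling of
    high-risk individuals into treatment.  Covariates (age, sex, birth year,
    deprivation index, 16 genotype PCs) carry small nonzero effects by
    default so downstream adjustment is exercised.
    """
    rng = child_rng(seed, "ehr")
    n = geno.n_individuals
    # genetically predicted expression per gene, standardized
    pred = {}
    for gene, sub in expr_weights.groupby("gene"):
        score = np.zeros(n)
        for _, row in sub.iterrows():
            score += row["weight"] * geno.dosages[:, geno.index_of(row["variant"])]
        sd = score.std()
        if sd > 0:
            pred[gene] = (score - score.mean()) / sd
    pred_df = pd.DataFrame(pred)

    age = rng.uniform(45, 80, n)
    sex = rng.integers(0, 2, n).astype(float)
    birth_year = 2020 - age - rng.uniform(0, 1, n)
    townsend = rng.standard_normal(n)
    pcs = rng.standard_normal((n, 16))
    cov_lin = covariate_scale * (
        0.5 * (age - age.mean()) / age.std()
        + sex
        - 0.3 * townsend
        + pcs[:, :4].sum(axis=1) * 0.2
    )

    latent_risk = rng.standard_normal(n)
    p_drug = expit(
        logit(drug_prevalence) + confounding_by_indication * latent_risk
    )
    drug = (rng.random(n) < p_drug).astype(float)

    inter = np.zeros(n)
    for gene, eff in truth.interaction_effects.items():
        if eff != 0.0 and gene in pred_df:
            inter = inter + eff * pred_df[gene].to_numpy()

    wmh = (
        drug_main_wmh * drug
        + drug * inter
        + cov_lin
        + 0.3 * latent_risk
        + rng.standard_normal(n)
    )
    eta = (
        logit(dementia_prevalence)
        + drug_main_dementia * drug
        + drug * inter
        + cov_lin
        + 0.3 * latent_risk
    )
    dementia = (rng.random(n) < expit(eta)).astype(float)

    table = pd.DataFrame(
        {
            "individual_id": [f"I{i + 1}" for i in range(n)],
            "wmh": wmh,
            "dementia": dementia,
            "drug": drug,
            "atc_class": atc_class,
            "age": age,
            "sex": sex,
            "birth_year": birth_year,
            "townsend": townsend,
        }
    )
    for k in range(16):
        table[f"pc{k + 1}"] = pcs[:, k]
    for gene in pred_df:
        table[f"expr_{gene}"] = pred_df[gene]
    n_exposed = int(drug.sum())
    return EhrCohort(table, n_exposed, n_exposed >= min_exposed, atc_class)


def simulate_paired_counts(
    n_pairs: int,
    nb_dispersion: float,
    log2fc: pd.DataFrame,
    seed: int = 0,
    *,
    n_cases: int | None = None,
    base_mean: float = 100.0,
    subject_sd: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired negative-binomial counts with a region x status design.

    ``n_pairs`` subjects each contribute two samples (cerebellum and
    DLPFC); the first ``n_cases`` subjects (default half) are cases.
    ``log2fc`` is a gene-indexed frame with columns ``region``, ``status``,
    ``interaction`` giving log2 fold changes relative to the baseline
    (cerebellum in controls).  Counts are NB with variance
    ``mu + alpha * mu**2`` around a per-subject baseline.
    """
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    if not {"region", "status", "interaction"} <= set(log2fc.columns):
        raise ValueError("log2fc needs columns region, status, interaction")
    rng = child_rng(seed, "counts")
    if n_cases is None:
        n_cases = n_pairs // 2
    genes = list(log2fc.index)
    subjects = [f"S{i + 1}" for i in range(n_pairs)]
    status = ["case" if i < n_cases else "control" for i in range(n_pairs)]
    rows = []
    for i, s in enumerate(subjects):
        for region in ("cerebellum", "DLPFC"):
            rows.append({"sample": f"{s}_{region}", "subject": s,
                         "region": region, "status": status[i]})
    design = pd.DataFrame(rows)
    subj_base = np.exp(subject_sd * rng.standard_normal(n_pairs))
    ln2 = np.log(2.0)
    counts = np.empty((len(genes), len(design)), dtype=np.int64)
    gene_base = base_mean * np.exp(0.5 * rng.standard_normal(len(genes)))
    for k, (_, samp) in enumerate(design.iterrows()):
        i = subjects.index(samp["subject"])
        is_dlpfc = float(samp["region"] == "DLPFC")
        is_case = float(samp["status"] == "case")
        lfc = (
            log2fc["region"].to_numpy() * is_dlpfc
            + log2fc["status"].to_numpy() * is_case
            + log2fc["interaction"].to_numpy() * is_dlpfc * is_case
        )
        mu = gene_base * subj_base[i] * np.exp(ln2 * lfc)
        # gamma-poisson mixture gives NB with var = mu + alpha mu^2
        shape = 1.0 / nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        counts[:, k] = rng.poisson(lam)
    cdf = pd.DataFrame(counts, index=genes, columns=design["sample"])
    return cdf, design
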