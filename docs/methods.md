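# Methods

`pharmtri` implements a cross-tissue triangulation pipeline for druggable
genes: given cis-QTL and GWAS summary statistics it prioritizes putatively
causal targets (PCTs) for an imaging trait (WMH burden) and a disease
outcome (dementia/AD), quantifies causal effects by Mendelian
randomization, scans for gene-by-medication interactions, profiles the
targets in paired and spatial expression data, and scores targetable
pathways with pharmagenic enrichment. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
evaluation does and does not establish.

## Fine-mapping (`pharmtri.finemap`)

Each cis region (variants within 500 kb of the gene boundary, MAF > 5%) is
modelled as carrying **exactly zero or one** causal variant. Per-variant
evidence is the Wakefield approximate Bayes factor

    ABF_j = sqrt(se_j^2 / (se_j^2 + W)) * exp( z_j^2 W / (2 (se_j^2 + W)) ),

with effect-size prior variance `W = 0.15^2` by default (suited to
molecular-trait effects in SD units; configurable). With per-variant prior
`pi0` (default `1/m`, one expected signal per tested region),

    PIP_j   = pi0 * ABF_j / (1 - pi0*m + pi0 * sum_k ABF_k)
    genePIP = pi0 * sum_k ABF_k / (1 - pi0*m + pi0 * sum_k ABF_k).

This replaces multi-signal stochastic-search fine-mapping deliberately:
the single-signal posterior is closed-form and is verified exhaustively
against enumeration of the `m+1` causal configurations (tolerance 1e-10).
The cost is that secondary signals in a region are folded into one
posterior; for the pipeline's purpose — producing variant and gene PIPs
to seed TWAS weights and instruments — this is sufficient, and multi-signal
backends can replace it behind the same result type. Credible sets are the
smallest PIP-sorted prefix reaching the requested normalized coverage;
ordering ties break by position then variant id, and PIP ties at the
inclusion boundary are all included, so the set is deterministic.

## Colocalization and INTACT (`pharmtri.coloc`)

Colocalization enumerates the standard five hypotheses (no association /
trait-1 only / trait-2 only / two distinct variants / one shared variant)
with per-variant Wakefield ABFs for both traits and priors
`p1 = p2 = 1e-4`, `p12 = 1e-5`. All sums run in log space (`logsumexp`;
H3 uses a log-difference identity), so regions with very strong signals do
not overflow. PP4 is taken as the gene-level colocalization probability
(GLCP).

TWAS association is `z = w'z_gwas / sqrt(w'Rw)` with PIP-weighted eQTL
effect weights and the region LD matrix `R`; a non-positive `w'Rw` is an
error, not a NaN.

The INTACT-style posterior treats the GLCP as the prior that the gene is
causal, floored at `t = 0.05` ("linear" prior; `expit` and `step`
alternatives are exposed), and multiplies it by a Bayes factor from the
TWAS z averaged over the shrinkage grid `K in {1, 2, 4, 8, 16}`:

    BF = mean_K sqrt(1/(1+K)) * exp( z^2 K / (2(1+K)) )
    posterior = pi*BF / (pi*BF + 1 - pi).

The floor keeps a strong TWAS signal from being vetoed outright by a
failed colocalization while still down-weighting it by ~20x relative to a
colocalized gene — this is exactly the mechanism that separates mediating
genes from pleiotropy-only decoys in the evaluation scenario. A gene is a
PCT when its posterior strictly exceeds 0.9 in at least one tissue.

Allele harmonization aligns the second study onto the first's effect
alleles, flips betas for swapped rows, and drops palindromic (A/T, C/G)
variants whose allele frequency lies in [0.4, 0.6]; harmonizing twice is a
no-op.

## Mendelian randomization (`pharmtri.mr`)

Instruments are oriented so the effect allele increases the exposure, and
every selection rule prunes greedily to pairwise r^2 < 0.1 with
deterministic tie-breaks (position, then id):

* expression instruments: fine-mapped variants ranked by PIP;
* protein instruments: P < 1e-3 (strict) within 1 Mb of the TSS, ranked by p;
* single-cell instruments: P < 1e-5 (strict), ranked by p.

Estimators (all per 1 SD of exposure):

* **Wald ratio** (single instrument): `Gamma/gamma` with first-order
  delta-method SE `sqrt(se_Gamma^2 + beta^2 se_gamma^2)/|gamma|`. The
  second-order correction is omitted; with the instrument strengths the
  selection rules admit, the first-order term dominates.
* **IVW** (fixed effect): inverse-variance-weighted mean of per-instrument
  ratios, `SE = 1/sqrt(sum w)`. By construction it coincides with the
  fixed-effect meta-analysis of the Wald ratios (checked as an invariant).
* **MR-Egger**: weighted regression of outcome on exposure betas with an
  intercept (average directional pleiotropy), weights `1/se_Gamma^2`. SEs
  carry the usual multiplicative random-effects scale `max(1, RSE)` so
  balanced pleiotropy widens the intervals instead of invalidating them.
* **Weighted median**: interpolated weighted median of the ratios; SE by
  parametric bootstrap (default 1000 draws, seeded), retaining the 50%
  breakdown property.
* **Robust profile score** (`raps_simplified`): solves
  `sum_j gamma_j * psi((Gamma_j - beta*gamma_j)/s_j(beta)) = 0` with the
  Huber psi (k = 1.345); root located by sign-change scan on [-10, 10] and
  Brent refinement; sandwich SE with the analytic `E[psi^2]` under a
  standard-normal residual. The overdispersion parameter of the full
  profile-score method is intentionally omitted — the estimator's role
  here is outlier-robust confirmation inside the decision rule, and the
  simplified score remains checkable against IVW in the no-pleiotropy
  limit.

**Triangulation**: an association is `supported` iff the IVW estimate is
significant at `alpha` (default 0.05, Bonferroni-divided by the number of
proteins tested by the caller), at least two pleiotropy-robust methods
agree with IVW in sign and significance, and colocalization PP4 >= 0.75
(inclusive). Missing prerequisites yield `insufficient`, not a silent
pass.

Observational protein validation uses a one-variance-component REML LMM,
`y = Xb + g + e`, `cov(g) = sigma_g^2 K` with `K` the doubled kinship
matrix: `K` is eigendecomposed once, the likelihood is profiled over
`delta = sigma_g^2/sigma_e^2` with a bounded scalar optimizer, and the
`delta -> 0` boundary is compared explicitly so unrelated samples
reproduce OLS exactly.

## Gene-by-medication interaction (`pharmtri.txewas`)

Two steps: (1) genetically predicted expression is a weighted dosage sum
per gene x tissue (weights are inputs; training them is out of scope),
standardized to SD units, with non-overlapping or zero-variance
predictions dropped and logged; (2) the interaction model

    outcome ~ drug + expr + drug:expr + age + sex + birth_year +
              deprivation + PC1..PC16

is fit with an identity link for the continuous outcome and a logit link
for the binary one. **All SEs are HC0 sandwich estimates** — the
misspecifications this guards against (heteroskedasticity, unmodelled
dose dependence) are exactly what the type-I-error study simulates.
Logistic separation raises an error so the fit can be excluded and
logged rather than reported with a meaningless SE. Drug classes enter
only if powered: >= 100 exposed individuals with a non-missing outcome
(the threshold is configurable; there is no canonical published value).

Multiplicity across genes and tissues uses the two-stage
Benjamini–Bogomolov procedure with tissues nested in genes (the
alternative nesting is a config switch): per-gene Simes p-values are
screened with BH at level `q`; within the `R` selected genes, tissues are
tested with BH at level `q*R/m`. Reported `hfdr_q` values are the
within-gene BH-adjusted p-values rescaled by `m/R`.

A significant binary-outcome interaction is summarized as the fractional
attenuation of the medication effect per SD of predicted expression,
`1 - exp(beta_int)`; for continuous outcomes the summary is
`-beta_int/beta_drug`, the fraction of the main effect offset per SD
(undefined and reported missing when the main effect is zero). The
binary-outcome formula is an interpretation choice, stated here
prominently: it reads the interaction coefficient as a multiplicative
modifier of the medication odds ratio.

The endogeneity screen regresses each predicted expression on medication
use, the trait, and the disease (main effects only); genes whose
expression predicts *treatment* are flagged, since their interactions may
reflect confounding-by-indication rather than effect modification.

## Expression profiling (`pharmtri.dge`)

Paired bulk DGE fits, per gene, a negative-binomial GLM with log link to
counts from two brain regions per subject: coefficients for status,
region, their interaction, and sum-to-zero subject contrasts nested in
status (so the status coefficient is a between-group contrast and the
baseline is cerebellum in controls); offsets are log median-of-ratios
size factors. Dispersions are method-of-moments per gene, shrunk 50%
(arithmetically) toward a least-squares `a0 + a1/mean` trend — a
deliberate simplification of full empirical-Bayes dispersion machinery
that keeps the estimator self-contained while stabilizing small-sample
genes. Wald p-values are normal-based; BH runs across genes. Relabeling
the baseline region flips the sign of region-linked log2FCs and nothing
else (tested). In the Poisson limit (dispersion -> 0) coefficients match
a Poisson GLM.

Q3 normalization divides each ROI by its upper-quartile expression and
rescales by the geometric mean of the upper quartiles; ROIs with zero Q3
are dropped. Group comparisons use Wilcoxon rank-sum tests — exact null
for group sizes under 30 without ties, normal approximation with
continuity correction otherwise, mid-ranks for ties, `p = 1` for
all-tied data — with BH within each cell type.

## Pharmagenic enrichment and PES (`pharmtri.pes`)

SNPs map to genes with strand-aware windows: 5 kb upstream and 1.5 kb
downstream of the gene body, where "upstream" follows transcription
direction. At each GWAS p-value threshold bin `P_T in {0.5, 0.05, 0.005}`
the gene statistic is `S = sum z_j^2` over the gene's SNPs with
`p < P_T`; genes with no surviving SNP are dropped at that bin. The null
of `S` under LD `R` is a quadratic form in correlated normals,
approximated by Satterthwaite moment matching (`E = m`,
`V = 2 sum r_ij^2`, scale `c = V/2E`, df `f = 2E^2/V`). This replaces
principal-components regression by design: it is closed-form and its
accuracy is verified against a Monte-Carlo quadratic-form oracle (true
0.05-tail ~0.051-0.052 across AR(1) rho 0.3-0.7). Degenerate checks are
exact: one SNP reproduces the SNP p-value, a perfectly duplicated SNP
changes nothing.

Competitive enrichment regresses gene z-statistics on set membership with
log gene length and log SNP count as covariates (a reduced covariate set
relative to full MAGMA), one-sided for positive enrichment, significant
at p < 0.001.

PES: pathway-mapped SNPs (de-duplicated across overlapping genes) with
`p < P_T` are pruned greedily in ascending-p order at r^2 < 0.1; the raw
score is the dosage-weighted sum of GWAS betas, standardized to cohort SD
units, cut at the empirical 20/40/60/80 percentiles. Disease association
uses logistic regression on quintile indicators (lowest quintile as
reference — effects are reported as odds ratios, which is what the model
estimates) plus a continuous per-SD model; the best `P_T` bin is the one
with the smallest continuous-model p. Quintiles with no cases or no
controls report unbounded CIs and are flagged.

## Synthetic cohorts (`pharmtri.synth`)

The generator emulates the statistical structure of the study's inputs
with every nonzero effect recorded in a `TruthLedger`:

* **Genotypes**: haplotype copy process per LD block — allele `j` copies
  allele `j-1` with probability `rho`, else a fresh Bernoulli(MAF) draw;
  dosage correlation is exactly `rho^|i-j|` within a block, blocks are
  independent, marginals are Hardy–Weinberg, MAF (one per block, drawn
  from (0.05, 0.5]) always exceeds 5%. A thresholded Gaussian copula was
  rejected for this role: discretizing a latent normal to {0,1,2}
  attenuates the correlation so strongly that high-LD blocks (dosage
  r^2 ~ 0.8) are unreachable at typical MAFs, whereas the copy process
  hits the target exactly with one parameter.
* **Molecular traits**: expression = causal cis dosages x per-allele
  effects + Gaussian noise, standardized to unit total variance so
  effects are in SD/allele; the protein channel shares the genetic
  component with independent noise, so eQTL and pQTL signals share causal
  variants by construction. Causal variants outside the declared cis
  window are a hard error.
* **GWAS**: trait = mediation x expression + direct variant effects +
  noise; binary disease via a logistic link on the standardized liability
  (a liability-threshold option exists; logistic is the default for
  interpretable odds ratios). Marginal scans are vectorized OLS and
  vectorized Newton logistic fits; under the full null the inflation
  factor is ~1.
* **EHR cohort**: age, sex, birth year, deprivation index and 16 PCs with
  small nonzero default effects (so adjustment is exercised); drug
  exposure optionally depends on a latent risk to emulate
  confounding-by-indication; outcomes carry drug main effects and
  expression-by-drug interactions from the ledger.
* **Paired counts**: gamma-Poisson (NB) counts with per-subject baselines
  and region/status/interaction log2FCs per gene.

Randomness derives from one root seed via fixed per-stream offsets;
identical seed and config give bit-identical outputs.

What the generator does **not** emulate: realistic human LD maps and
allele-frequency spectra, imputation uncertainty, sex chromosomes,
population stratification, relatedness (beyond the explicit family-block
kinship test), ICD-based phenotype curation, and real pathway topology.
Passing the evaluation therefore establishes internal statistical
correctness — calibration, error control, and recovery under the model's
own assumptions — not performance on real cohort data.

## Standard evaluation conditions (`pharmtri.scenarios`)

Problem sizes are the package's standard study conditions, chosen to be
population-cohort-like while remaining desk-scale:

* **Prioritization**: 100 genes x 20 SNPs (AR(1) rho 0.5), eQTL cohort
  n = 5,000, GWAS cohort n = 20,000; 5 mediating genes (eQTL 0.5
  SD/allele, mediation 0.15 trait-SD per expression-SD), 10
  pleiotropy-only decoys whose trait effect (matched per-allele size)
  sits on a variant at LD r = rho^10 from the eQTL, 85 nulls. Expected
  outcome: all mediating genes above posterior 0.9, decoys and nulls
  below.
* **MR calibration**: 500 replicates, 30 instruments (exposure effects
  0.3-0.7, SEs 0.02/0.05), true effect 0.3; CI coverage for all four
  primary estimators within [0.92, 0.98]; Egger intercept coverage under
  balanced pleiotropy (SD 0.02).
* **TxEWAS**: type-I error of the interaction test at n = 2,000 x 500
  replicates under a null whose residual SD grows with drug x |expr|;
  attenuation recovery at n = 20,000 with exp(beta_int) = 0.267 (i.e.
  73.3%).
* **hFDR**: 200 panels of 50 genes x 4 tissues, 10% true genes with
  signal in half their tissues (z ~ 4).
* **DGE**: 20 subject pairs, dispersion 0.1, 300 genes of which 20% carry
  an interaction log2FC of +-1 split evenly up/down. The even split is
  essential, not cosmetic: one-directional DE in a large gene fraction
  shifts the median-of-ratios size factors and biases *every*
  normalizing estimator (~0.5 log2 units at a 50% DE fraction).
* **Gene statistic**: 2,000 null genes, 20 SNPs, AR(1) rho 0.5.
* **PES**: 40 genes x 10 SNPs (rho 0.3), 10-gene planted pathway with
  0.15 SD/allele causal variants, disease generated from the true
  pathway score with a top-vs-bottom-quintile OR of 2.2 at n = 20,000.
  Effects are strong enough that GWAS weight noise stays small relative
  to signal; even so the quintile OR of the *estimated* score is mildly
  attenuated (~5% on the log scale) relative to the generative truth —
  an inherent property of polygenic scoring with estimated weights, and
  the reason weaker effect/stronger LD settings cannot meet a
  CI-recovery target regardless of implementation.

## Known limitations

* Single-signal fine-mapping folds allelic heterogeneity into one PIP
  vector; regions with several independent QTLs will under-attribute.
* The INTACT prior function/truncation and the powered-class threshold
  are package defaults, not published constants.
* The Satterthwaite gene statistic matches two moments; extreme tails
  (p << 1e-4) are approximate, though conservative in our checks.
* The MR suite assumes two-sample summary statistics with independent
  errors; sample overlap is not modelled.
* PES quintile contrasts are attenuated by weight-estimation noise, as
  quantified above; real-data odds ratios should be read as lower bounds
  under comparable power.
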