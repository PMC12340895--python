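# pharmtri

Cross-tissue triangulation of putatively causal drug targets (PCTs) from
QTL and GWAS summary statistics.

White matter hyperintensities (WMH) — the MRI hallmark of cerebral small
vessel disease — causally contribute to dementia risk, which makes
druggable genes influencing WMH attractive repurposing candidates. Given
cis-QTL summary statistics across tissues and GWAS summary statistics for
a trait and a disease, `pharmtri` triangulates such targets through five
arms, each usable on its own from Python:

1. **Fine-mapping** (`pharmtri.finemap`) — single-signal Bayesian
   fine-mapping with Wakefield approximate Bayes factors: variant- and
   gene-level posterior inclusion probabilities (PIPs) and credible sets.
2. **Colocalization + INTACT** (`pharmtri.coloc`) — enumeration
   colocalization (PP0–PP4), TWAS z-scores
   `z = w'z / sqrt(w'Rw)`, and the INTACT posterior
   `pi·BF / (pi·BF + 1 − pi)` with the colocalization probability as a
   truncated prior; genes with posterior > 0.9 are PCTs.
3. **Mendelian randomization** (`pharmtri.mr`) — Wald ratio, fixed-effect
   IVW, MR-Egger, weighted median and a simplified robust profile score,
   LD-pruned (r² < 0.1) instrument selection from eQTLs/pQTLs/single-cell
   eQTLs, fixed-effect pQTL meta-analysis, a kinship-aware REML LMM, and
   the triangulation rule: IVW + ≥2 concordant robust methods + PP4 ≥ 0.75.
4. **TxEWAS pharmacogenomics** (`pharmtri.txewas`) — gene-by-medication
   interaction regressions with HC0 sandwich variance, hierarchical
   (Benjamini–Bogomolov) FDR across genes × tissues, and the attenuation
   summary `1 − exp(beta_int)` per SD of predicted expression.
5. **Expression profiling & pathways** (`pharmtri.dge`, `pharmtri.pes`) —
   paired region×status negative-binomial DGE, Q3-normalized Wilcoxon
   cell-type comparisons, MAGMA-style gene statistics at GWAS p-value
   threshold bins, competitive gene-set enrichment, and pathway polygenic
   scores (PES) with quintile disease-risk association.

`pharmtri.synth` generates every input format with a known
`TruthLedger` (LD-blocked genotypes, cis-regulated expression/protein
levels, GWAS summary statistics, EHR-style phenotype tables, paired
RNA-seq counts), so the whole pipeline is testable without restricted
cohort data; `pharmtri.io` reads and writes the standard formats (GWAS
TSV, dosage TSV, BED, GMT, phenotype TSV, LD matrices) with strict schema
validation and run manifests.

See `docs/methods.md` for the models, defaults, and limitations.

## Worked example

`examples/` contains one narrative script per arm. The core one:

```bash
python examples/01_prioritize_targets.py
```

builds a 20-gene synthetic study (two genes mediate the trait through
expression, one is a pleiotropy-only decoy) and prints:

```
Prioritized targets (INTACT posterior > 0.9):
gene  best_posterior     tissues  n_tissues
 G02             1.0 whole_blood          1
 G01             1.0 whole_blood          1

G01: TWAS z =  +6.02, coloc PP4 = 1.000, posterior = 1.000
G02: TWAS z =  -7.37, coloc PP4 = 1.000, posterior = 1.000
G03: TWAS z =  +1.98, coloc PP4 = 0.000, posterior = 0.092
G04: TWAS z =  -0.57, coloc PP4 = 0.013, posterior = 0.027
```

G01/G02 are the mediating genes: their eQTL and GWAS signals share a
causal variant, so colocalization (PP4) and the INTACT posterior are
high. G03 is the decoy — its trait signal sits on a different, weakly
linked variant, colocalization fails, and INTACT down-weights the strong
TWAS z to 0.09. The remaining nulls score near zero.

The other scripts demonstrate MR with triangulation
(`02_mendelian_randomization.py`), the gene-by-drug interaction scan with
its ~73% attenuation recovery (`03_gene_by_drug_interaction.py`), paired
differential expression and spatial Wilcoxon tests
(`04_paired_expression.py`), and pathway enrichment with PES quintile
odds ratios (`05_pathway_scores.py`).

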