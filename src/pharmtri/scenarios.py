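"""Standard evaluation scenarios with known ground truth.

Each function builds a self-contained synthetic experiment, runs the
relevant pipeline arm end to end, and returns the measured quantities
together with the truth used to generate the data.  The acceptance script
and the test suite both consume these scenarios so the numbers they report
are recomputed from scratch on every run.

Problem sizes follow the package's standard study conditions: GWAS cohorts
of 20,000, an eQTL cohort of 5,000 (population-cohort scale), 100 candidate
genes of which 5 mediate the trait and 10 are pleiotropy-only decoys,
500-replicate calibration studies, and 20-subject paired RNA-seq designs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from pharmtri import coloc, dge, finemap, mr, pes, synth, txewas

__all__ = [
    "pct_prioritization_scenario",
    "finemap_enumeration_check",
    "mr_coverage_study",
    "egger_balanced_pleiotropy_study",
    "txewas_type1_study",
    "txewas_attenuation_scenario",
    "hfdr_fdp_study",
    "dge_recovery_scenario",
    "gene_stat_calibration_study",
    "pes_end_to_end_scenario",
]


# ---------------------------------------------------------------------------
# PCT prioritization: fine-mapping -> TWAS -> coloc -> INTACT
# ---------------------------------------------------------------------------

def pct_prioritization_scenario(
    seed: int,
    *,
    n_gwas: int = 20_000,
    n_eqtl: int = 5_000,
    n_genes: int = 100,
    n_mediating: int = 5,
    n_pleiotropy: int = 10,
    snps_per_gene: int = 20,
    rho: float = 0.5,
    eqtl_beta: float = 0.5,
    mediation_effect: float = 0.15,
    direct_effect: float = 0.075,
    posterior_threshold: float = 0.90,
) -> dict:
    """The standard target-prioritization scenario.

    100 candidate genes each occupy their own AR(1) LD block; every gene
    has one causal cis-eQTL (variant 6 of its block, 0.5 SD/allele).  The
    first 5 genes mediate the trait through expression (0.15 trait SD per
    expression SD); the next 10 are pleiotropy-only decoys whose trait
    signal sits on a *different*, nearly unlinked variant (variant 16,
    r = rho**10) with a per-allele effect matched to the mediated genes;
    the rest are null.  Separate cohorts supply the eQTL summary statistics
    (n=5,000) and the trait GWAS (n=20,000).  The scenario fine-maps each
    gene, computes TWAS z with PIP-weighted eQTL weights, colocalizes
    eQTL and GWAS signals, and scores every gene with the INTACT posterior.
    """
    m_total = n_genes * snps_per_gene
    spec = synth.LdBlockSpec(m_total, snps_per_gene, rho)
    geno_gwas = synth.simulate_genotypes(spec, n_gwas, seed)
    geno_eqtl = synth.simulate_genotypes(spec, n_eqtl, seed + 1)

    truth = synth.TruthLedger()
    genes = []
    spacing = 1_000
    for g in range(n_genes):
        name = f"G{g + 1:03d}"
        j0 = g * snps_per_gene
        start = int(geno_gwas.positions[j0])
        end = int(geno_gwas.positions[j0 + snps_per_gene - 1])
        genes.append(synth.GeneModel(name, "1", start, end,
                                     cis_radius=snps_per_gene * spacing))
        causal = geno_gwas.variant_ids[j0 + 5]
        truth.record_eqtl(name, causal, eqtl_beta)
        if g < n_mediating:
            truth.mediation_effects[name] = mediation_effect
        elif g < n_mediating + n_pleiotropy:
            pv = geno_gwas.variant_ids[j0 + 15]
            truth.direct_trait_effects[pv] = direct_effect

    expr_gwas, _ = synth.simulate_molecular_traits(geno_gwas, genes, truth,
                                                   seed=seed)
    expr_eqtl, _ = synth.simulate_molecular_traits(geno_eqtl, genes, truth,
                                                   seed=seed + 1)
    gwas = synth.simulate_gwas(geno_gwas, expr_gwas, truth, seed=seed,
                               scan_disease=False)["trait"]

    results: list[coloc.IntactResult] = []
    per_gene = {}
    for g, gm in enumerate(genes):
        j0, j1 = g * snps_per_gene, (g + 1) * snps_per_gene
        ids = geno_eqtl.variant_ids[j0:j1]
        escan = synth.marginal_ols_scan(
            geno_eqtl.dosages[:, j0:j1], expr_eqtl[gm.gene].to_numpy())
        estats = pd.DataFrame({
            "SNP": ids, "POS": geno_eqtl.positions[j0:j1],
            "BETA": escan["BETA"], "SE": escan["SE"], "P": escan["P"],
        })
        fine = finemap.compute_pips(estats, gene=gm.gene, maf_filter=None)
        gsub = gwas.iloc[j0:j1]
        ld = geno_gwas.ld[j0:j1, j0:j1]
        w = fine.variants["pip"].to_numpy() * fine.variants["BETA"].to_numpy()
        z_gwas = (gsub["BETA"] / gsub["SE"]).to_numpy()
        zt = coloc.twas_z(w, z_gwas, ld)
        cres = coloc.coloc_abf(estats[["SNP", "BETA", "SE"]],
                               gsub[["SNP", "BETA", "SE"]])
        ires = coloc.intact_posterior(zt, cres.pp4, gene=gm.gene,
                                      tissue="whole_blood")
        results.append(ires)
        per_gene[gm.gene] = {"fine": fine, "coloc": cres, "intact": ires,
                             "eqtl_stats": estats, "gwas_stats": gsub}

    pcts = coloc.prioritize_pcts(results, threshold=posterior_threshold)
    mediating = set(truth.mediating_genes())
    pleio = {genes[g].gene for g in range(n_mediating, n_mediating + n_pleiotropy)}
    found = set(pcts["gene"]) if not pcts.empty else set()
    posteriors = {r.gene: r.posterior for r in results}
    return {
        "truth": truth,
        "genes": genes,
        "pcts": pcts,
        "per_gene": per_gene,
        "posteriors": posteriors,
        "n_mediating_recovered": len(found & mediating),
        "n_mediating": n_mediating,
        "n_false_positives": len(found - mediating),
        "pleiotropy_below_threshold_frac": float(np.mean(
            [posteriors[g] <= posterior_threshold for g in pleio]))
        if pleio else float("nan"),
    }


def finemap_enumeration_check(seed: int, *, n_regions: int = 50,
                              max_variants: int = 10) -> float:
    """Max |PIP difference| between compute_pips and brute-force enumeration
    over random small regions.  Should be ~1e-15 (tolerance 1e-10)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_regions):
        m = int(rng.integers(1, max_variants + 1))
        region = pd.DataFrame({
            "SNP": [f"rs{i}" for i in range(m)],
            "POS": np.arange(m) * 100 + 1,
            "BETA": rng.normal(0, 0.3, m),
            "SE": rng.uniform(0.05, 0.2, m),
        })
        fine = finemap.compute_pips(region, maf_filter=None)
        oracle_pips, oracle_gene = finemap.enumerate_pips_bruteforce(region)
        worst = max(worst,
                    float(np.max(np.abs(fine.variants["pip"].to_numpy()
                                        - oracle_pips))),
                    abs(fine.gene_pip - oracle_gene))
    return worst


# ---------------------------------------------------------------------------
# MR calibration
# ---------------------------------------------------------------------------

def _draw_instruments(rng: np.random.Generator, n_inst: int, beta: float,
                      se_x: float, se_y: float,
                      pleiotropy_sd: float = 0.0) -> pd.DataFrame:
    gamma = rng.uniform(0.3, 0.7, n_inst)
    alpha = pleiotropy_sd * rng.standard_normal(n_inst) if pleiotropy_sd else 0.0
    return pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(n_inst)],
        "exposure_beta": gamma + se_x * rng.standard_normal(n_inst),
        "exposure_se": se_x,
        "outcome_beta": beta * gamma + alpha + se_y * rng.standard_normal(n_inst),
        "outcome_se": se_y,
    })


def mr_coverage_study(
    seed: int,
    *,
    n_reps: int = 500,
    true_beta: float = 0.3,
    n_inst: int = 30,
    se_x: float = 0.02,
    se_y: float = 0.05,
) -> dict[str, float]:
    """95% CI coverage of the true causal effect for each estimator.

    Valid instruments (no pleiotropy); the Wald ratio uses a single strong
    instrument per replicate, the multi-instrument methods use 30.
    """
    rng = np.random.default_rng(seed)
    hits = {m: 0 for m in ("wald", "ivw", "egger", "weighted_median")}
    for r in range(n_reps):
        inst = _draw_instruments(rng, n_inst, true_beta, se_x, se_y)
        single = _draw_instruments(rng, 1, true_beta, se_x, se_y)
        ests = {
            "wald": mr.wald_ratio(single),
            "ivw": mr.ivw(inst),
            "egger": mr.mr_egger(inst),
            "weighted_median": mr.weighted_median(inst, n_boot=500, seed=r),
        }
        for name, est in ests.items():
            lo, hi = est.ci()
            hits[name] += int(lo <= true_beta <= hi)
    return {m: h / n_reps for m, h in hits.items()}


def egger_balanced_pleiotropy_study(
    seed: int,
    *,
    n_reps: int = 500,
    true_beta: float = 0.3,
    n_inst: int = 30,
    pleiotropy_sd: float = 0.02,
) -> float:
    """Fraction of replicates whose Egger intercept CI covers zero under
    balanced (mean-zero) pleiotropy."""
    rng = np.random.default_rng(seed)
    cover = 0
    for _ in range(n_reps):
        inst = _draw_instruments(rng, n_inst, true_beta, 0.02, 0.05,
                                 pleiotropy_sd=pleiotropy_sd)
        est = mr.mr_egger(inst)
        lo = est.egger_intercept - 1.96 * est.egger_intercept_se
        hi = est.egger_intercept + 1.96 * est.egger_intercept_se
        cover += int(lo <= 0.0 <= hi)
    return cover / n_reps


# ---------------------------------------------------------------------------
# TxEWAS
# ---------------------------------------------------------------------------

def txewas_type1_study(
    seed: int,
    *,
    n_reps: int = 500,
    n: int = 2_000,
    alpha: float = 0.05,
) -> float:
    """Interaction-test type-I error under a heteroskedastic null.

    No true interaction; the residual SD of the continuous outcome grows
    with |expression| among the treated, the misspecification the sandwich
    variance exists to absorb.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    covars = ["age", "sex"]
    for _ in range(n_reps):
        drug = (rng.random(n) < 0.3).astype(float)
        expr = rng.standard_normal(n)
        age = rng.uniform(45, 80, n)
        sex = rng.integers(0, 2, n).astype(float)
        noise_sd = 1.0 + 1.5 * drug * np.abs(expr)
        y = (0.3 * drug + 0.1 * expr + 0.01 * (age - 60) + 0.1 * sex
             + noise_sd * rng.standard_normal(n))
        pheno = pd.DataFrame({"wmh": y, "drug": drug, "expr": expr,
                              "age": age, "sex": sex})
        fit = txewas.fit_interaction(pheno, "wmh", "expr", covariates=covars)
        rejections += int(fit.p_interaction < alpha)
    return rejections / n_reps


def txewas_attenuation_scenario(
    seed: int,
    *,
    n: int = 20_000,
    interaction_or: float = 0.267,
) -> dict:
    """Recover the attenuation of a medication's dementia risk.

    The generator plants a gene-by-drug interaction of exp(beta_int) =
    0.267 on the dementia log-odds, so one SD of predicted expression
    should attenuate the medication effect by ~73.3%.
    """
    spec = synth.LdBlockSpec(15, 5, 0.5)
    geno = synth.simulate_genotypes(spec, n, seed)
    weights = pd.DataFrame([
        {"gene": f"T{g + 1}", "tissue": "artery", "variant": geno.variant_ids[g * 5 + j],
         "weight": w}
        for g in range(3)
        for j, w in enumerate([0.5, 0.3, 0.2, -0.2, 0.1])
    ])
    truth = synth.TruthLedger()
    truth.interaction_effects["T1"] = float(np.log(interaction_or))
    cohort = synth.simulate_ehr_cohort(geno, weights, truth, seed=seed)
    pred, dropped = txewas.impute_expression(
        geno.dosages, geno.variant_ids, weights)
    pheno = pd.concat([cohort.table, pred.add_prefix("pred_")], axis=1)
    fit = txewas.fit_interaction(pheno, "dementia", "pred_T1@artery",
                                 gene="T1", tissue="artery",
                                 atc_class=cohort.atc_class)
    att = txewas.attenuation(fit)
    return {"fit": fit, "attenuation": att, "cohort": cohort,
            "true_attenuation": 1.0 - interaction_or,
            "dropped": dropped}


def hfdr_fdp_study(
    seed: int,
    *,
    n_panels: int = 200,
    n_genes: int = 50,
    n_tissues: int = 4,
    frac_true_genes: float = 0.1,
    q: float = 0.05,
    effect_z: float = 4.0,
) -> dict[str, float]:
    """Realized false discovery proportion of the hierarchical FDR.

    Each panel has 10% of genes with a true signal in half their tissues;
    the FDP is the fraction of selected gene-tissue pairs that are null,
    averaged over panels.
    """
    rng = np.random.default_rng(seed)
    n_true = int(round(frac_true_genes * n_genes))
    fdps = []
    n_selected = 0
    for _ in range(n_panels):
        rows = []
        for g in range(n_genes):
            for t in range(n_tissues):
                is_true = g < n_true and t < n_tissues // 2
                if is_true:
                    z = effect_z + rng.standard_normal()
                    p = float(2 * stats.norm.sf(abs(z)))
                else:
                    p = float(rng.random())
                rows.append({"gene": f"G{g}", "tissue": f"T{t}",
                             "p": p, "is_true": is_true})
        panel = pd.DataFrame(rows)
        res = txewas.hierarchical_fdr(panel[["gene", "tissue", "p"]], q=q)
        sel = res["selected"].to_numpy()
        n_sel = int(sel.sum())
        n_selected += n_sel
        if n_sel:
            false = int((sel & ~panel["is_true"].to_numpy()).sum())
            fdps.append(false / n_sel)
        else:
            fdps.append(0.0)
    return {"mean_fdp": float(np.mean(fdps)), "q": q,
            "mean_selected": n_selected / n_panels}


# ---------------------------------------------------------------------------
# Paired differential expression
# ---------------------------------------------------------------------------

def dge_recovery_scenario(
    seed: int,
    *,
    n_pairs: int = 20,
    dispersion: float = 0.1,
    n_up: int = 30,
    n_down: int = 30,
    n_null: int = 240,
    true_log2fc: float = 1.0,
) -> dict:
    """Recovery of a planted region-by-status interaction log2FC.

    DE genes are a minority (20%) split evenly between up- and
    down-regulated interactions, so the median-of-ratios size factors
    stay anchored by the non-DE majority, as the normalization assumes.
    """
    n_true = n_up + n_down
    genes = [f"g{i}" for i in range(n_true + n_null)]
    log2fc = pd.DataFrame(0.0, index=genes,
                          columns=["region", "status", "interaction"])
    jcol = log2fc.columns.get_loc("interaction")
    log2fc.iloc[:n_up, jcol] = true_log2fc
    log2fc.iloc[n_up:n_true, jcol] = -true_log2fc
    log2fc["region"] = 0.3  # mild regional shift everywhere
    counts, design = synth.simulate_paired_counts(
        n_pairs, dispersion, log2fc, seed=seed)
    res = dge.fit_paired_nb(counts, design)
    signed = np.concatenate([
        res.loc[genes[:n_up], "log2fc_interaction"].to_numpy(),
        -res.loc[genes[n_up:n_true], "log2fc_interaction"].to_numpy(),
    ])
    est_null = res.loc[genes[n_true:], "log2fc_interaction"]
    return {
        "results": res,
        "median_interaction_log2fc": float(np.median(signed)),
        "true_log2fc": true_log2fc,
        "median_null_log2fc": float(est_null.median()),
        "null_p": res.loc[genes[n_true:], "p_interaction"],
    }


# ---------------------------------------------------------------------------
# Pharmagenic enrichment
# ---------------------------------------------------------------------------

def gene_stat_calibration_study(
    seed: int,
    *,
    n_genes: int = 2_000,
    m: int = 20,
    rho: float = 0.5,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of the Satterthwaite gene statistic under AR(1) LD."""
    rng = np.random.default_rng(seed)
    R = rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m))).astype(float)
    L = np.linalg.cholesky(R)
    rejections = 0
    for g in range(n_genes):
        z = L @ rng.standard_normal(m)
        gs = pes.gene_statistic(z, R)
        rejections += int(gs.gene_p < alpha)
    return {"type1_error": rejections / n_genes, "alpha": alpha}


def pes_end_to_end_scenario(
    seed: int,
    *,
    n: int = 20_000,
    n_genes: int = 40,
    snps_per_gene: int = 10,
    n_pathway_genes: int = 10,
    per_snp_beta: float = 0.15,
    top_quintile_or: float = 2.2,
    rho: float = 0.3,
) -> dict:
    """Planted-pathway enrichment and PES quintile risk recovery.

    The first 10 genes form a coagulation-like druggable pathway; each
    carries one causal trait variant (0.15 SD/allele -- strong enough
    that GWAS weight noise stays small relative to the signal, so the PES
    is a faithful proxy for the true pathway burden).  The trait GWAS is
    run in-cohort; gene statistics and the competitive enrichment test are
    computed at each P_T bin (0.5, 0.05, 0.005), with the pathway's best
    bin selected by smallest enrichment p -- bins in which the P_T filter
    removes the contrast are skipped.  The pathway PES is scored at each
    usable bin, standardized and cut into quintiles, and the best bin for
    the risk model is chosen by the smallest continuous per-SD p.  Disease
    status is generated from the *true* pathway genetic score with a
    log-odds slope chosen so the expected top-vs-bottom-quintile odds
    ratio is ``top_quintile_or``.
    """
    m_total = n_genes * snps_per_gene
    spec = synth.LdBlockSpec(m_total, snps_per_gene, rho)
    geno = synth.simulate_genotypes(spec, n, seed)
    truth = synth.TruthLedger()
    pathway_genes = [f"P{g + 1:02d}" for g in range(n_pathway_genes)]
    null_genes = [f"N{g + 1:02d}" for g in range(n_genes - n_pathway_genes)]
    all_genes = pathway_genes + null_genes
    causal_idx = []
    for g, name in enumerate(all_genes):
        if g < n_pathway_genes:
            j = g * snps_per_gene + 4
            truth.direct_trait_effects[geno.variant_ids[j]] = per_snp_beta
            causal_idx.append(j)
    truth.pathway_membership["coagulation_like"] = pathway_genes

    gwas = synth.simulate_gwas(geno, None, truth, seed=seed,
                               scan_disease=False)["trait"]

    spacing = 1_000
    annotation = pd.DataFrame([
        {"gene": name, "chrom": "1",
         "start": int(geno.positions[g * snps_per_gene]),
         "end": int(geno.positions[(g + 1) * snps_per_gene - 1]),
         "strand": "+"}
        for g, name in enumerate(all_genes)
    ])
    gene_map = pes.map_snps_to_genes(gwas, annotation, upstream=spacing // 2,
                                     downstream=spacing // 2)

    pos_of = dict(zip(geno.variant_ids, range(m_total)))

    def _gene_stats_at(p_threshold: float) -> pd.DataFrame:
        rows = []
        for g, name in enumerate(all_genes):
            snps = gene_map.get(name, [])
            idx = np.array([pos_of[s] for s in snps])
            sub = gwas.iloc[idx]
            z = (sub["BETA"] / sub["SE"]).to_numpy()
            try:
                gs = pes.gene_statistic(z, geno.ld[np.ix_(idx, idx)],
                                        gene=name, p_threshold=p_threshold,
                                        gwas_p=sub["P"].to_numpy())
            except ValueError:  # no SNP below the threshold
                continue
            rows.append({"gene": name, "gene_z": gs.gene_z,
                         "log_length": float(np.log(snps_per_gene * spacing)),
                         "log_nsnps": float(np.log(gs.n_snps))})
        return pd.DataFrame(rows)

    enr_by_bin = {}
    null_by_bin = {}
    stats_by_bin = {}
    for pt in pes.P_THRESHOLD_BINS:
        gene_stats_pt = _gene_stats_at(pt)
        stats_by_bin[pt] = gene_stats_pt
        try:
            enr_by_bin[pt] = pes.competitive_enrichment(
                gene_stats_pt, pathway_genes, p_threshold_bin=pt,
                pathway="coagulation_like")
            null_by_bin[pt] = pes.competitive_enrichment(
                gene_stats_pt, null_genes[:n_pathway_genes],
                p_threshold_bin=pt, pathway="matched_null")
        except ValueError:  # filter removed the contrast at this bin
            continue
    best_bin = min(enr_by_bin, key=lambda pt: enr_by_bin[pt]["one_sided_p"])
    enr = enr_by_bin[best_bin]
    null_enr = null_by_bin[best_bin]
    gene_stats = stats_by_bin[best_bin]

    # disease from the true pathway genetic score
    rng = synth.child_rng(seed, "misc")
    true_score = geno.dosages[:, causal_idx].sum(axis=1)
    true_score = (true_score - true_score.mean()) / true_score.std()
    # top/bottom quintile means of a standard normal are ~ +/-1.400
    slope = float(np.log(top_quintile_or) / 2.80)
    eta = stats.norm.ppf(0.2) + slope * true_score
    disease = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)

    pathway_snps = [s for g in pathway_genes for s in gene_map.get(g, [])]
    ld_df = pd.DataFrame(geno.ld, index=geno.variant_ids,
                         columns=geno.variant_ids)
    assoc_by_bin = {}
    profile_by_bin = {}
    for pt in pes.P_THRESHOLD_BINS:
        try:
            prof = pes.compute_pes(geno.dosages, geno.variant_ids, gwas,
                                   pathway_snps, ld_df, p_threshold=pt,
                                   pathway="coagulation_like")
        except ValueError:  # no SNP survives at this bin
            continue
        profile_by_bin[pt] = prof
        assoc_by_bin[pt] = pes.quintile_association(prof, disease)
    best_pes_bin = min(assoc_by_bin,
                       key=lambda pt: assoc_by_bin[pt]["per_sd_p"])
    return {
        "enrichment": enr,
        "null_enrichment": null_enr,
        "best_enrichment_bin": best_bin,
        "best_pes_bin": best_pes_bin,
        "gene_stats": gene_stats,
        "profile": profile_by_bin[best_pes_bin],
        "association": assoc_by_bin[best_pes_bin],
        "true_top_quintile_or": top_quintile_or,
        "disease": disease,
    }
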