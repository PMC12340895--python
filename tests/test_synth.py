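"""Generator properties: LD structure, determinism, effect recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pharmtri import synth


class TestSimulateGenotypes:
    def test_independent_variants_have_no_ld(self):
        spec = synth.LdBlockSpec(10, 1, 0.0)
        geno = synth.simulate_genotypes(spec, 10_000, seed=1)
        r = np.corrcoef(geno.dosages.T)
        off = r[np.triu_indices(10, 1)]
        assert np.mean(off**2) < 0.01

    def test_adjacent_r2_matches_generating_correlation(self):
        spec = synth.LdBlockSpec(10, 10, 0.9, maf_range=(0.2, 0.4))
        geno = synth.simulate_genotypes(spec, 10_000, seed=2)
        r = np.corrcoef(geno.dosages.T)
        adjacent_r2 = np.array([r[j, j + 1] ** 2 for j in range(9)])
        assert abs(adjacent_r2.mean() - 0.81) < 0.05

    def test_same_seed_is_bit_identical(self):
        spec = synth.LdBlockSpec(20, 5, 0.5)
        a = synth.simulate_genotypes(spec, 500, seed=3)
        b = synth.simulate_genotypes(spec, 500, seed=3)
        assert np.array_equal(a.dosages, b.dosages)
        assert np.array_equal(a.maf, b.maf)

    def test_dosages_in_range_and_maf_above_threshold(self):
        spec = synth.LdBlockSpec(30, 10, 0.3)
        geno = synth.simulate_genotypes(spec, 5_000, seed=4)
        assert geno.dosages.min() >= 0 and geno.dosages.max() <= 2
        emp_maf = np.minimum(geno.dosages.mean(0) / 2, 1 - geno.dosages.mean(0) / 2)
        assert (geno.maf > 0.05).all()
        assert np.allclose(emp_maf, geno.maf, atol=0.03)

    @pytest.mark.parametrize("bad", [
        dict(n_variants=10, block_size=5, rho=1.0),
        dict(n_variants=10, block_size=5, rho=-0.1),
        dict(n_variants=10, block_size=5, rho=0.5, maf_range=(0.01, 0.3)),
        dict(n_variants=10, block_size=5, rho=0.5, maf_range=(0.4, 0.6)),
        dict(n_variants=0, block_size=5, rho=0.5),
    ])
    def test_degenerate_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            synth.LdBlockSpec(**bad)

    def test_ld_matrix_is_psd_with_unit_diagonal(self):
        spec = synth.LdBlockSpec(15, 5, 0.7)
        R = spec.ld_matrix()
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert np.linalg.eigvalsh(R).min() > -1e-10


class TestMolecularTraits:
    def _setup(self, beta, n=5_000, maf=0.3, seed=5):
        spec = synth.LdBlockSpec(5, 5, 0.4, maf_range=(maf, maf))
        geno = synth.simulate_genotypes(spec, n, seed=seed)
        gene = synth.GeneModel("G1", "1", 1_000, 5_000)
        truth = synth.TruthLedger()
        truth.record_eqtl("G1", "rs3", beta)
        expr, prot = synth.simulate_molecular_traits(geno, [gene], truth, seed=seed)
        return geno, expr, prot, truth

    def test_null_gene_expression_independent_of_genotype(self):
        spec = synth.LdBlockSpec(5, 5, 0.4)
        geno = synth.simulate_genotypes(spec, 3_000, seed=6)
        gene = synth.GeneModel("G1", "1", 1_000, 5_000)
        expr, _ = synth.simulate_molecular_traits(
            geno, [gene], synth.TruthLedger(), seed=6)
        scan = synth.marginal_ols_scan(geno.dosages, expr["G1"].to_numpy())
        assert scan["P"].min() > 1e-4  # no real signal among 5 variants

    def test_marginal_beta_recovered(self):
        geno, expr, _, _ = self._setup(0.5)
        scan = synth.marginal_ols_scan(geno.dosages, expr["G1"].to_numpy())
        assert abs(scan["BETA"].iloc[2] - 0.5) < 0.05

    def test_variance_explained_matches_theory(self):
        geno, expr, _, _ = self._setup(0.4)
        d = geno.dosages[:, 2]
        maf = d.mean() / 2
        expected = 2 * maf * (1 - maf) * 0.4**2
        r2 = np.corrcoef(d, expr["G1"])[0, 1] ** 2
        assert abs(r2 - expected / expr["G1"].var()) < 0.03

    def test_protein_shares_causal_variant(self):
        geno, expr, prot, _ = self._setup(0.5)
        scan_e = synth.marginal_ols_scan(geno.dosages, expr["G1"].to_numpy())
        scan_p = synth.marginal_ols_scan(geno.dosages, prot["G1"].to_numpy())
        assert scan_e["P"].idxmin() == scan_p["P"].idxmin() == 2

    def test_causal_variant_outside_cis_window_rejected(self):
        spec = synth.LdBlockSpec(5, 5, 0.4)
        geno = synth.simulate_genotypes(spec, 100, seed=7)
        gene = synth.GeneModel("G1", "1", 1_000_000, 1_001_000, cis_radius=100)
        truth = synth.TruthLedger()
        truth.record_eqtl("G1", "rs1", 0.5)  # rs1 at position 1000
        with pytest.raises(ValueError, match="outside cis window"):
            synth.simulate_molecular_traits(geno, [gene], truth)


class TestSimulateGwas:
    def test_null_inflation_factor_near_one(self):
        spec = synth.LdBlockSpec(5_000, 10, 0.3)
        geno = synth.simulate_genotypes(spec, 2_000, seed=8)
        out = synth.simulate_gwas(geno, None, synth.TruthLedger(), seed=8,
                                  scan_disease=False)
        lam = synth.genomic_inflation(out["trait"]["P"].to_numpy())
        assert 0.95 <= lam <= 1.05

    def test_mediated_gene_eqtl_is_trait_associated(self):
        spec = synth.LdBlockSpec(10, 5, 0.4, maf_range=(0.3, 0.3))
        geno = synth.simulate_genotypes(spec, 10_000, seed=9)
        genes = [synth.GeneModel("G1", "1", 1_000, 5_000),
                 synth.GeneModel("G2", "1", 6_000, 10_000)]
        truth = synth.TruthLedger()
        truth.record_eqtl("G1", "rs3", 0.5)
        truth.record_eqtl("G2", "rs8", 0.5)
        truth.mediation_effects["G1"] = 0.2
        expr, _ = synth.simulate_molecular_traits(geno, genes, truth, seed=9)
        gwas = synth.simulate_gwas(geno, expr, truth, seed=9,
                                   scan_disease=False)["trait"]
        assert gwas["P"].iloc[2] < 1e-6  # mediated eQTL
        assert gwas["P"].iloc[7] > 1e-3  # null gene's eQTL

    def test_logistic_scan_recovers_or_three(self):
        rng = synth.child_rng(10, "misc")
        n = 20_000
        d = rng.binomial(2, 0.3, n).astype(float)
        eta = stats.norm.ppf(0.2) + np.log(3.0) * d
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        scan = synth.marginal_logistic_scan(d[:, None], y)
        assert abs(scan["BETA"].iloc[0] - np.log(3.0)) < 2.5 * scan["SE"].iloc[0]

    def test_liability_model_matches_prevalence(self):
        spec = synth.LdBlockSpec(10, 5, 0.4)
        geno = synth.simulate_genotypes(spec, 5_000, seed=11)
        out = synth.simulate_gwas(geno, None, synth.TruthLedger(), seed=11,
                                  disease_model="liability", scan_disease=False)
        assert abs(out["phenotypes"]["disease"].mean() - 0.2) < 0.02


class TestEhrCohort:
    def _cohort(self, n=2_000, interaction=0.0, confounding=0.0, seed=12):
        spec = synth.LdBlockSpec(5, 5, 0.4)
        geno = synth.simulate_genotypes(spec, n, seed=seed)
        weights = pd.DataFrame({
            "gene": "T1", "tissue": "artery",
            "variant": geno.variant_ids, "weight": [0.5, 0.3, 0.2, -0.2, 0.1],
        })
        truth = synth.TruthLedger()
        if interaction:
            truth.interaction_effects["T1"] = interaction
        return synth.simulate_ehr_cohort(
            geno, weights, truth, seed=seed,
            confounding_by_indication=confounding)

    def test_schema_complete(self):
        cohort = self._cohort()
        cols = set(cohort.table.columns)
        needed = {"individual_id", "wmh", "dementia", "drug", "age", "sex",
                  "birth_year", "townsend"} | {f"pc{i}" for i in range(1, 17)}
        assert needed <= cols

    def test_drug_main_effect_recovered(self):
        cohort = self._cohort(n=20_000)
        import statsmodels.api as sm
        t = cohort.table
        X = sm.add_constant(t[["drug", "age", "sex", "townsend"]])
        res = sm.GLM(t["dementia"], X, family=sm.families.Binomial()).fit()
        lo = res.params["drug"] - 1.96 * res.bse["drug"]
        hi = res.params["drug"] + 1.96 * res.bse["drug"]
        assert lo <= np.log(3.0) <= hi

    def test_underpowered_exposure_flagged(self):
        spec = synth.LdBlockSpec(5, 5, 0.4)
        geno = synth.simulate_genotypes(spec, 50, seed=13)
        weights = pd.DataFrame({"gene": "T1", "tissue": "artery",
                                "variant": geno.variant_ids,
                                "weight": [1, 0, 0, 0, 0.0]})
        cohort = synth.simulate_ehr_cohort(geno, weights, synth.TruthLedger(),
                                           seed=13, drug_prevalence=0.2)
        assert cohort.n_exposed < 100 and not cohort.powered


class TestPairedCounts:
    def test_null_interaction_p_uniform(self):
        genes = [f"g{i}" for i in range(100)]
        log2fc = pd.DataFrame(0.0, index=genes,
                              columns=["region", "status", "interaction"])
        counts, design = synth.simulate_paired_counts(10, 0.1, log2fc, seed=14)
        from pharmtri import dge
        res = dge.fit_paired_nb(counts, design)
        p = res["p_interaction"].dropna()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_nonpositive_dispersion_rejected(self):
        log2fc = pd.DataFrame(0.0, index=["g1"],
                              columns=["region", "status", "interaction"])
        with pytest.raises(ValueError, match="dispersion"):
            synth.simulate_paired_counts(4, 0.0, log2fc)

    def test_deterministic_given_seed(self):
        log2fc = pd.DataFrame(0.0, index=["g1", "g2"],
                              columns=["region", "status", "interaction"])
        a, _ = synth.simulate_paired_counts(4, 0.1, log2fc, seed=15)
        b, _ = synth.simulate_paired_counts(4, 0.1, log2fc, seed=15)
        pd.testing.assert_frame_equal(a, b)


def test_truth_ledger_roundtrip_and_completeness():
    truth = synth.TruthLedger()
    truth.record_eqtl("G1", "rs1", 0.5)
    truth.record_eqtl("G2", "rs9", -0.3)
    truth.record_eqtl("G3", "rs5", 0.0)  # zero effects are not recorded
    truth.mediation_effects["G1"] = 0.2
    truth.pathway_membership["pw"] = ["G1", "G2"]
    assert "G3" not in truth.eqtl_effects
    assert truth.mediating_genes() == ["G1"]
    back = synth.TruthLedger.from_json(truth.to_json())
    assert back.eqtl_effects == truth.eqtl_effects
    assert back.pathway_membership == truth.pathway_membership
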