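"""MR estimators, instrument selection, meta-analysis, triangulation, LMM."""

import numpy as np
import pandas as pd
import pytest

from pharmtri import mr


def make_instruments(bx, sx, by, sy, pos=None):
    m = len(bx)
    return pd.DataFrame({
        "SNP": [f"rs{i + 1}" for i in range(m)],
        "POS": pos if pos is not None else np.arange(m) * 1000 + 1,
        "exposure_beta": bx, "exposure_se": sx,
        "outcome_beta": by, "outcome_se": sy,
    })


def ld_frame(r, snps):
    return pd.DataFrame(r, index=snps, columns=snps)


class TestInstrumentSelection:
    def test_perfect_proxies_keep_higher_pip(self):
        cand = make_instruments([0.5, 0.5], [0.1] * 2, [0.2] * 2, [0.05] * 2)
        cand["pip"] = [0.4, 0.6]
        ld = ld_frame([[1.0, 1.0], [1.0, 1.0]], ["rs1", "rs2"])
        kept = mr.select_instruments_eqtl(cand, ld)
        assert list(kept["SNP"]) == ["rs2"]

    def test_pip_tie_broken_by_position(self):
        cand = make_instruments([0.5, 0.5], [0.1] * 2, [0.2] * 2, [0.05] * 2,
                                pos=[2000, 1000])
        cand["pip"] = [0.5, 0.5]
        ld = ld_frame([[1.0, 0.99], [0.99, 1.0]], ["rs1", "rs2"])
        kept = mr.select_instruments_eqtl(cand, ld)
        assert list(kept["SNP"]) == ["rs2"]  # smaller position wins the tie

    def test_independent_candidates_all_kept(self):
        cand = make_instruments([0.5] * 3, [0.1] * 3, [0.2] * 3, [0.05] * 3)
        cand["pip"] = [0.5, 0.4, 0.3]
        kept = mr.select_instruments_eqtl(
            cand, ld_frame(np.eye(3), cand["SNP"]))
        assert len(kept) == 3

    def test_greedy_matches_bruteforce_on_toy_r2(self, rng):
        """The greedy PIP-ordered solution equals an independent re-walk."""
        for _ in range(10):
            m = 6
            a = rng.uniform(-1, 1, (m, m))
            r = np.corrcoef(a @ a.T + np.eye(m))
            cand = make_instruments(rng.uniform(0.2, 0.8, m), [0.1] * m,
                                    rng.normal(0, 0.2, m), [0.05] * m)
            cand["pip"] = rng.uniform(0, 1, m)
            ld = ld_frame(r, cand["SNP"])
            kept = list(mr.select_instruments_eqtl(cand, ld, pip_min=0.0)["SNP"])
            order = cand.sort_values(["pip", "POS", "SNP"],
                                     ascending=[False, True, True])["SNP"]
            manual = []
            for s in order:
                if all(ld.loc[s, k] ** 2 < 0.1 for k in manual):
                    manual.append(s)
            assert sorted(kept) == sorted(manual)

    def test_pqtl_filters(self):
        pqtl = make_instruments([0.5] * 4, [0.1] * 4, [0.2] * 4, [0.05] * 4,
                                pos=[1_000, 900_000, 1_000 + 1_000_001,
                                     500_000])
        pqtl["P"] = [1e-5, 1e-4, 1e-8, 0.001]  # last: boundary, strict
        ld = ld_frame(np.eye(4), pqtl["SNP"])
        kept = mr.select_instruments_pqtl(pqtl, tss=1_000, ld=ld)
        # rs3 is beyond 1 Mb of the TSS, rs4 sits exactly at P = 0.001
        assert sorted(kept["SNP"]) == ["rs1", "rs2"]

    def test_sc_threshold_strict(self):
        sc = make_instruments([0.5] * 2, [0.1] * 2, [0.2] * 2, [0.05] * 2)
        sc["P"] = [1e-5, 0.9e-5]
        kept = mr.select_instruments_sc(sc, ld_frame(np.eye(2), sc["SNP"]))
        assert list(kept["SNP"]) == ["rs2"]

    def test_empty_candidates_pass_through(self):
        cand = make_instruments([0.5], [0.1], [0.2], [0.05])
        cand["pip"] = [0.01]
        out = mr.select_instruments_eqtl(
            cand, ld_frame(np.eye(1), cand["SNP"]))
        assert out.empty


class TestWaldRatio:
    def test_unit_exposure_identity(self):
        est = mr.wald_ratio(make_instruments([1.0], [0.0], [0.3], [0.07]))
        assert est.beta == pytest.approx(0.3)
        assert est.se == pytest.approx(0.07)

    def test_delta_method_value(self):
        est = mr.wald_ratio(make_instruments([0.5], [0.1], [0.2], [0.05]))
        assert est.beta == pytest.approx(0.4, rel=1e-12)
        expected_se = (1 / 0.5) * np.sqrt(0.05**2 + 0.4**2 * 0.1**2)
        assert est.se == pytest.approx(expected_se, rel=1e-12)
        assert expected_se == pytest.approx(0.128, abs=5e-4)

    def test_allele_flip_invariance(self):
        a = mr.wald_ratio(make_instruments([0.5], [0.1], [0.2], [0.05]))
        b = mr.wald_ratio(make_instruments([-0.5], [0.1], [-0.2], [0.05]))
        assert a.beta == pytest.approx(b.beta)
        assert a.se == pytest.approx(b.se)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError, match="Wald ratio undefined"):
            mr.wald_ratio(make_instruments([0.0], [0.1], [0.2], [0.05]))

    def test_requires_exactly_one_instrument(self):
        inst = make_instruments([0.5, 0.4], [0.1] * 2, [0.2] * 2, [0.05] * 2)
        with pytest.raises(ValueError):
            mr.wald_ratio(inst)


class TestIvw:
    def test_identical_instruments_return_common_ratio(self):
        inst = make_instruments([0.5, 0.5], [0.1] * 2, [0.2] * 2, [0.05] * 2)
        assert mr.ivw(inst).beta == pytest.approx(0.4)

    def test_weighted_mean_arithmetic(self):
        # ratios 0.4 (se 0.12806) and 0.6 (se 0.2)
        inst = make_instruments([0.5, 1.0], [0.1, 0.0], [0.2, 0.6], [0.05, 0.2])
        est = mr.ivw(inst)
        w1 = 1 / ((1 / 0.5) * np.sqrt(0.05**2 + 0.4**2 * 0.1**2)) ** 2
        w2 = 1 / 0.2**2
        assert est.beta == pytest.approx((w1 * 0.4 + w2 * 0.6) / (w1 + w2), rel=1e-9)
        assert est.se == pytest.approx(1 / np.sqrt(w1 + w2), rel=1e-9)
        assert est.beta == pytest.approx(0.458, abs=2e-3)
        assert est.se == pytest.approx(0.108, abs=2e-3)

    def test_zero_weight_instrument_is_inert(self):
        base = make_instruments([0.5, 0.6], [0.05] * 2, [0.2, 0.25], [0.04] * 2)
        extra = pd.concat([base, make_instruments([0.5], [0.0], [9.9], [1e6])],
                          ignore_index=True)
        assert mr.ivw(extra).beta == pytest.approx(mr.ivw(base).beta, abs=1e-6)

    def test_equals_meta_of_wald_ratios(self):
        inst = make_instruments([0.5, 0.7, 0.4], [0.05] * 3,
                                [0.2, 0.3, 0.18], [0.04, 0.05, 0.03])
        est = mr.ivw(inst)
        singles = [mr.wald_ratio(inst.iloc[[i]]) for i in range(3)]
        beta, se, _ = mr.fixed_effect_meta([(s.beta, s.se) for s in singles])
        assert est.beta == pytest.approx(beta, rel=1e-12)
        assert est.se == pytest.approx(se, rel=1e-12)

    def test_minimum_two_instruments(self):
        with pytest.raises(ValueError):
            mr.ivw(make_instruments([0.5], [0.1], [0.2], [0.05]))


class TestMrEgger:
    def test_line_through_origin(self):
        bx = np.array([0.3, 0.5, 0.8])
        inst = make_instruments(bx, [0.01] * 3, 0.4 * bx, [0.05] * 3)
        est = mr.mr_egger(inst)
        assert est.beta == pytest.approx(0.4, abs=1e-9)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-9)

    def test_directional_offset_lands_in_intercept(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.3, 0.8, 20)
        by = 0.4 * bx + rng.normal(0, 0.05, 20)
        inst = make_instruments(bx, [0.01] * 20, by, [0.05] * 20)
        base = mr.mr_egger(inst)
        shifted = inst.copy()
        shifted["outcome_beta"] += 0.1
        est = mr.mr_egger(shifted)
        assert est.egger_intercept == pytest.approx(base.egger_intercept + 0.1,
                                                    abs=1e-9)
        assert est.beta == pytest.approx(base.beta, abs=1e-9)

    def test_minimum_three_instruments(self):
        with pytest.raises(ValueError):
            mr.mr_egger(make_instruments([0.5, 0.6], [0.1] * 2,
                                         [0.2, 0.2], [0.05] * 2))


class TestWeightedMedian:
    def test_constant_ratios(self):
        inst = make_instruments([0.5, 0.4, 0.8], [0.05] * 3,
                                [0.25, 0.2, 0.4], [0.04] * 3)
        assert mr.weighted_median(inst, seed=1).beta == pytest.approx(0.5, abs=1e-9)

    def test_bootstrap_reproducible(self):
        inst = make_instruments([0.5, 0.4, 0.8], [0.05] * 3,
                                [0.2, 0.25, 0.3], [0.04] * 3)
        a = mr.weighted_median(inst, seed=11)
        b = mr.weighted_median(inst, seed=11)
        assert a.se == b.se

    def test_breakdown_under_half_invalid(self):
        """<=50% grossly pleiotropic instruments barely move the estimate."""
        rng = np.random.default_rng(5)
        n = 50
        bx = rng.uniform(0.3, 0.8, n)
        by = 0.3 * bx + rng.normal(0, 0.01, n)
        by[:20] += rng.uniform(0.3, 0.6, 20)  # 40% invalid, large pleiotropy
        inst = make_instruments(bx, [0.01] * n, by, [0.01] * n)
        est = mr.weighted_median(inst, seed=2)
        assert abs(est.beta - 0.3) < 0.05


class TestRapsSimplified:
    def test_agrees_with_ivw_without_pleiotropy(self):
        rng = np.random.default_rng(8)
        n = 50
        bx = rng.uniform(0.4, 0.8, n)
        inst = make_instruments(bx, [0.005] * n,
                                0.3 * bx + rng.normal(0, 0.01, n), [0.01] * n)
        est = mr.raps_simplified(inst)
        assert abs(est.beta - mr.ivw(inst).beta) < 1e-3

    def test_outlier_resistance_vs_ivw(self):
        rng = np.random.default_rng(9)
        n = 20
        bx = rng.uniform(0.4, 0.8, n)
        clean = make_instruments(bx, [0.005] * n,
                                 0.3 * bx + rng.normal(0, 0.01, n), [0.01] * n)
        dirty = clean.copy()
        dirty.loc[0, "outcome_beta"] += 1.0  # gross outlier
        ivw_shift = abs(mr.ivw(dirty).beta - mr.ivw(clean).beta)
        raps_shift = abs(mr.raps_simplified(dirty).beta
                         - mr.raps_simplified(clean).beta)
        assert raps_shift < 0.2 * ivw_shift

    def test_single_instrument_rejected(self):
        with pytest.raises(ValueError):
            mr.raps_simplified(make_instruments([0.5], [0.1], [0.2], [0.05]))


class TestFixedEffectMeta:
    def test_two_identical_studies(self):
        beta, se, _ = mr.fixed_effect_meta([(0.3, 0.1), (0.3, 0.1)])
        assert beta == pytest.approx(0.3)
        assert se == pytest.approx(0.1 / np.sqrt(2), abs=1e-4)

    def test_single_study_identity(self):
        beta, se, _ = mr.fixed_effect_meta([(0.25, 0.08)])
        assert (beta, se) == (0.25, 0.08)

    def test_three_studies_hand_computed(self):
        studies = [(0.2, 0.1), (0.4, 0.2), (0.1, 0.05)]
        w = [100.0, 25.0, 400.0]
        expected = (0.2 * 100 + 0.4 * 25 + 0.1 * 400) / 525
        beta, se, _ = mr.fixed_effect_meta(studies)
        assert beta == pytest.approx(expected, rel=1e-12)
        assert se == pytest.approx(1 / np.sqrt(525), rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mr.fixed_effect_meta([])


class TestTriangulate:
    def _est(self, method, beta, p, n=5):
        se = abs(beta) / 3 if p < 0.05 else abs(beta)
        return mr.MrEstimate(method, beta, se, p, n)

    def test_concordant_evidence_supported(self):
        ests = {"ivw": self._est("ivw", 0.3, 1e-4),
                "egger": self._est("egger", 0.25, 1e-3),
                "weighted_median": self._est("weighted_median", 0.28, 1e-3)}
        out = mr.triangulate(ests, pp4=0.9)
        assert out.verdict == "supported"

    def test_pp4_boundary_is_inclusive(self):
        ests = {"ivw": self._est("ivw", 0.3, 1e-4),
                "egger": self._est("egger", 0.25, 1e-3),
                "weighted_median": self._est("weighted_median", 0.28, 1e-3)}
        assert mr.triangulate(ests, pp4=0.75).verdict == "supported"
        out = mr.triangulate(ests, pp4=0.74)
        assert out.verdict == "not_supported" and "coloc" in out.reasons

    def test_discordant_robust_methods(self):
        ests = {"ivw": self._est("ivw", 0.3, 1e-4),
                "egger": self._est("egger", -0.25, 1e-3),
                "weighted_median": self._est("weighted_median", 0.28, 1e-3)}
        assert mr.triangulate(ests, pp4=0.9).verdict == "not_supported"

    def test_missing_methods_insufficient(self):
        assert mr.triangulate({"ivw": self._est("ivw", 0.3, 1e-4)},
                              pp4=0.9).verdict == "insufficient"


class TestKinshipLmm:
    def test_identity_kinship_matches_ols(self, rng):
        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1.0, 0.5] + rng.standard_normal(n)
        b, se, _ = mr.kinship_lmm(y, X, np.eye(n))
        import statsmodels.api as sm
        ols = sm.OLS(y, X).fit()
        assert b == pytest.approx(ols.params[1], abs=1e-6)
        assert se == pytest.approx(ols.bse[1], rel=1e-4)

    def test_heritability_recovered_in_family_blocks(self):
        rng = np.random.default_rng(17)
        n_fam, fam_size = 200, 4
        n = n_fam * fam_size
        block = np.full((fam_size, fam_size), 0.5) + 0.5 * np.eye(fam_size)
        K = np.kron(np.eye(n_fam), block)
        L = np.linalg.cholesky(block)
        sigma_g2, sigma_e2 = 0.4, 0.6
        g = np.concatenate([
            np.sqrt(sigma_g2) * (L @ rng.standard_normal(fam_size))
            for _ in range(n_fam)])
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [0.5, 0.3] + g + np.sqrt(sigma_e2) * rng.standard_normal(n)
        b, se, p, sg2, se2 = mr.kinship_lmm(y, X, K, return_variance=True)
        h2 = sg2 / (sg2 + se2)
        assert abs(h2 - 0.4) < 0.1
        assert abs(b - 0.3) < 3 * se

    def test_non_psd_kinship_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            mr.kinship_lmm(np.zeros(2), np.ones((2, 1)), K, coef_index=0)


def test_orientation_and_harmonization_idempotent():
    inst = make_instruments([-0.5, 0.4], [0.1] * 2, [0.2, -0.1], [0.05] * 2)
    once = mr.orient_instruments(inst)
    twice = mr.orient_instruments(once)
    pd.testing.assert_frame_equal(once, twice)
    assert (once["exposure_beta"] > 0).all()
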