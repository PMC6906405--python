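"""Allele counting, logistic SVA, QC lambda, and the selection rules."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from netseed.annotation import VariantKey
from netseed.association import (
    AnalysisConfig,
    VariantAssociation,
    allele_stats,
    bonferroni_threshold,
    crude_odds_ratio,
    genomic_lambda,
    logistic_sva,
    select_candidate_threshold,
    select_prs_variants,
)
from netseed.simulate import GenotypePanel


def _panel_from_dosages(case_dos, ctrl_dos):
    """Assemble a bare panel (one variant) from explicit dosage vectors."""
    dos = np.concatenate([case_dos, ctrl_dos]).astype(float).reshape(-1, 1)
    n = len(dos)
    pheno = np.concatenate([np.ones(len(case_dos), dtype=int),
                            np.zeros(len(ctrl_dos), dtype=int)])
    cov = pd.DataFrame({"age": np.full(n, 60.0), "sex": np.zeros(n, dtype=int)},
                       index=[f"S{i}" for i in range(n)])
    return GenotypePanel(
        samples=[f"S{i}" for i in range(n)],
        variants=[VariantKey("1", 100, "A", "G", "v1")],
        dosages=dos, phenotype=pheno, covariates=cov)


class TestAlleleStats:
    def test_replication_cohort_frequencies(self):
        """10 alt alleles in 60 cases and 676 in 8214 controls."""
        cases = np.zeros(60)
        cases[:10] = 1          # ten heterozygous carriers
        controls = np.zeros(8214)
        controls[:676] = 1
        panel = _panel_from_dosages(cases, controls)
        c_a, c_u, f_a, f_u = allele_stats(panel, 0)
        assert (c_a, c_u) == (10, 676)
        assert round(f_a, 3) == 0.083
        assert round(f_u, 5) == 0.04115

    def test_missing_genotypes_shrink_denominator(self):
        """74 alleles over 433 genotyped of 439 cases give frequency 0.0855."""
        cases = np.zeros(439)
        cases[:74] = 1
        cases[433:] = np.nan    # six failed genotypes
        panel = _panel_from_dosages(cases, np.zeros(855))
        c_a, _, f_a, _ = allele_stats(panel, 0)
        assert c_a == 74
        assert round(f_a, 4) == 0.0855
        assert round(74 / (2 * f_a)) == 433

    def test_all_missing_group_flagged_nan(self):
        cases = np.full(10, np.nan)
        panel = _panel_from_dosages(cases, np.ones(10))
        _, _, f_a, f_u = allele_stats(panel, 0)
        assert np.isnan(f_a) and f_u == 0.5


class TestCrudeOddsRatio:
    def test_symmetric_table_is_one(self):
        or_, flag = crude_odds_ratio(5, 100, 5, 100)
        assert or_ == pytest.approx(1.0) and not flag

    def test_cross_product(self):
        or_, _ = crude_odds_ratio(10, 120, 676, 16428)
        assert round(or_, 3) == 2.118

    def test_zero_cell_correction(self):
        or_, flag = crude_odds_ratio(0, 100, 5, 100)
        assert flag and 0 < or_ < 1


class TestLogisticSva:
    def test_monomorphic_skipped(self):
        panel = _panel_from_dosages(np.zeros(50), np.zeros(50))
        (res,) = logistic_sva(panel, AnalysisConfig())
        assert res.status == "monomorphic"
        assert np.isnan(res.or_estimate)

    def test_binary_dosage_matches_crude_odds_ratio(self):
        rng = np.random.default_rng(0)
        cases = (rng.random(300) < 0.3).astype(float)
        ctrls = (rng.random(500) < 0.15).astype(float)
        panel = _panel_from_dosages(cases, ctrls)
        config = AnalysisConfig(n_pcs=0)
        # constant age/sex columns are dropped inside the fit
        (res,) = logistic_sva(panel, config)
        c1, c0 = int(cases.sum()), int(ctrls.sum())
        crude, _ = crude_odds_ratio(c1, len(cases), c0, len(ctrls))
        assert res.or_estimate == pytest.approx(crude, abs=1e-6)

    def test_null_panel_p_values_behave(self, small_null_panel):
        results = logistic_sva(small_null_panel, AnalysisConfig())
        ps = [r.p_value for r in results if r.ok]
        assert len(ps) == 30
        assert all(0 < p <= 1 for p in ps)
        assert 0.2 < np.mean(ps) < 0.8

    def test_lrt_close_to_wald_for_common_variant(self, risk_panel):
        wald = logistic_sva(risk_panel, AnalysisConfig())
        lrt = logistic_sva(risk_panel, AnalysisConfig(), use_lrt=True)
        assert np.isclose(np.log10(wald[0].p_value), np.log10(lrt[0].p_value),
                          atol=1.0)

    def test_age_covariate_requires_column(self, small_null_panel):
        with pytest.raises(ValueError, match="covariate"):
            logistic_sva(small_null_panel, AnalysisConfig(),
                         extra_covariates=("weight",))


class TestGenomicLambda:
    def test_all_half_is_exactly_one(self):
        assert genomic_lambda([0.5] * 7) == pytest.approx(1.0, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=501)
        doubled = chi2.sf(2 * chi2.isf(p, 1), 1)
        assert genomic_lambda(doubled) == pytest.approx(2 * genomic_lambda(p),
                                                        rel=1e-9)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=101)
        assert genomic_lambda(p) == genomic_lambda(sorted(p))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_lambda([])


class TestCandidateSelection:
    def test_lowest_threshold_with_enough_hits(self):
        rng = np.random.default_rng(3)
        p = np.concatenate([rng.uniform(1e-6, 4e-4, 11),
                            rng.uniform(0.01, 1.0, 89)])
        config = AnalysisConfig(candidate_thresholds=(0.05, 0.0005),
                                selection_min_variants=11)
        t, selected = select_candidate_threshold(list(p), config)
        assert t == 0.0005 and len(selected) == 11

    def test_fallback_to_largest_threshold(self):
        config = AnalysisConfig(candidate_thresholds=(0.05, 0.0005),
                                selection_min_variants=11)
        t, selected = select_candidate_threshold([0.2, 0.5, 0.01], config)
        assert t == 0.05 and selected == [2]

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.beta(0.3, 3, size=200)
        config = AnalysisConfig()
        t, selected = select_candidate_threshold(list(p), config)
        for cand in sorted(config.candidate_thresholds):
            count = sum(1 for x in p if x < cand)
            if count >= config.selection_min_variants:
                assert t == cand and len(selected) == count
                break

    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 11, 0.0045), (0.05, 1, 0.05), (0.05, 2, 0.025)])
    def test_bonferroni(self, alpha, m, expected):
        assert round(bonferroni_threshold(alpha, m), 4) == expected

    def test_bonferroni_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _va(id_, pos, p, f_a, or_=1.5):
    key = VariantKey("1", pos, "A", "G", id_)
    return VariantAssociation(key=key, or_estimate=or_, p_value=p,
                              c_a=0, c_u=0, f_a=f_a, f_u=0.0, n_eff=1000)


class TestSelectPrsVariants:
    """Replays the published candidate table's keep/drop pattern."""

    DISCOVERY = [
        _va("rs117509001", 1, 4.805e-4, 0.0148, 5.979),
        _va("rs2230288", 2, 8.927e-6, 0.0855, 2.208),
        _va("rs2627037", 3, 4.346e-4, 0.1378, 1.616),
        _va("rs922984", 4, 3.337e-4, 0.1355, 1.637),
        _va("rs2291310", 5, 3.337e-4, 0.1355, 1.637),
        _va("rs2291311", 6, 3.337e-4, 0.1355, 1.637),
        _va("rs2291312", 7, 3.337e-4, 0.1355, 1.637),
        _va("rs140485496", 8, 1.978e-4, 0.0353, 2.666),
        _va("rs113574896", 9, 1.122e-11, 0.0966, 3.987),
        _va("chr10_105048270_AGAG_A", 10, 5.064e-5, 0.0294, 5.722),
        _va("rs1865493", 11, 5.161e-5, 0.0957, 0.548),
    ]
    REPLICATION = [
        _va("rs117509001", 1, 1.0, 0.0),
        _va("rs2230288", 2, 0.0237, 0.083),
        _va("rs2627037", 3, 0.0526, 0.167),
        _va("rs922984", 4, 0.0441, 0.167),
        _va("rs2291310", 5, 0.0435, 0.167),
        _va("rs2291311", 6, 0.0438, 0.167),
        _va("rs2291312", 7, 0.0441, 0.167),
        _va("rs140485496", 8, 1.0, 0.0),
        _va("rs113574896", 9, 1.0, 0.0),
        _va("chr10_105048270_AGAG_A", 10, 0.0191, 0.05),
        _va("rs1865493", 11, 0.5418, 0.15),
    ]

    def _keys(self, *ids):
        by_id = {r.key.id: r.key for r in self.DISCOVERY}
        return [by_id[i] for i in ids]

    def test_reproduces_published_two_variant_selection(self):
        ttn_block = {"members": self._keys(
            "rs2627037", "rs922984", "rs2291310", "rs2291311", "rs2291312"),
            "representative": self._keys("rs2291312")[0]}
        chosen = select_prs_variants(
            self.DISCOVERY, self.REPLICATION,
            ld_blocks=[ttn_block],
            exclusions=self._keys("rs113574896", "chr10_105048270_AGAG_A"),
            config=AnalysisConfig(prs_maf_tolerance=0.5),
            p_cutoff=0.0005)
        assert {k.id for k in chosen} == {"rs2230288", "rs2291312"}

    def test_ld_block_default_representative_is_smallest_p(self):
        block = {"members": self._keys("rs2627037", "rs922984", "rs2291310",
                                       "rs2291311", "rs2291312")}
        chosen = select_prs_variants(
            self.DISCOVERY, self.REPLICATION, ld_blocks=[block],
            config=AnalysisConfig(prs_maf_tolerance=0.5), p_cutoff=0.0005)
        ttn = [k for k in chosen if k.id.startswith("rs9") or "229131" in k.id
               or k.id == "rs2627037"]
        assert len(ttn) == 1
        assert ttn[0].id in {"rs922984", "rs2291310", "rs2291311", "rs2291312"}

    def test_frequency_screen_drops_discordant_variant(self):
        chosen = select_prs_variants(
            self.DISCOVERY, self.REPLICATION,
            config=AnalysisConfig(prs_maf_tolerance=0.5), p_cutoff=0.0005)
        ids = {k.id for k in chosen}
        assert "rs113574896" not in ids     # 0.0966 vs ~0: far beyond tolerance
        assert "rs1865493" not in ids       # 0.0957 vs 0.15: rel. diff 0.57
        assert "rs2230288" in ids

    def test_degenerate_config_is_p_and_frequency_filter(self):
        chosen = select_prs_variants(
            self.DISCOVERY, self.REPLICATION, ld_blocks=[], exclusions=[],
            config=AnalysisConfig(prs_maf_tolerance=0.5), p_cutoff=0.0005)
        assert {k.id for k in chosen} == {
            "rs2230288", "rs2627037", "rs922984", "rs2291310", "rs2291311",
            "rs2291312"}

    def test_unknown_representative_rejected(self):
        block = {"members": self._keys("rs2627037"),
                 "representative": self._keys("rs2230288")[0]}
        with pytest.raises(ValueError):
            select_prs_variants(self.DISCOVERY, self.REPLICATION,
                                ld_blocks=[block], p_cutoff=0.0005)
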