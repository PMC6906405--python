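"""Polygenic risk score arithmetic, summaries and replication association."""

import numpy as np
import pandas as pd
import pytest

from netseed.annotation import VariantKey
from netseed.association import AnalysisConfig, logistic_sva
from netseed.prs import PrsModel, compute_prs, prs_association, prs_quartile_summary
from netseed.simulate import CohortSimSpec, GenotypePanel, VariantSimSpec, simulate_cohort


def _two_variant_panel(dosages, phenotype=None):
    dosages = np.asarray(dosages, dtype=float)
    n = len(dosages)
    pheno = np.zeros(n, dtype=int) if phenotype is None else np.asarray(phenotype)
    cov = pd.DataFrame({"age": np.full(n, 55.0), "sex": np.zeros(n)},
                       index=[f"S{i}" for i in range(n)])
    return GenotypePanel(
        samples=[f"S{i}" for i in range(n)],
        variants=[VariantKey("1", 1, "A", "G", "vA"),
                  VariantKey("1", 2, "A", "G", "vB")],
        dosages=dosages, phenotype=pheno, covariates=cov)


MODEL = PrsModel.from_odds_ratios(
    [VariantKey("1", 1, "A", "G", "vA"), VariantKey("1", 2, "A", "G", "vB")],
    [2.208, 1.637])


class TestComputePrs:
    def test_published_range_endpoints(self):
        """One GBA-like copy plus two TTN-like copies score 1.78; no copies 0."""
        panel = _two_variant_panel([[1, 2], [0, 0]])
        scores, _ = compute_prs(panel, MODEL)
        assert round(scores[0], 2) == 1.78
        assert scores[1] == 0.0

    def test_neutral_odds_ratio_contributes_nothing(self):
        model = PrsModel.from_odds_ratios(MODEL.variants, [1.0, 1.637])
        panel = _two_variant_panel([[2, 1]])
        scores, _ = compute_prs(panel, model)
        assert scores[0] == pytest.approx(np.log(1.637))

    def test_missing_dosage_contributes_zero_and_flags(self):
        panel = _two_variant_panel([[np.nan, 2], [1, 1]])
        scores, flags = compute_prs(panel, MODEL)
        assert scores[0] == pytest.approx(2 * np.log(1.637))
        assert flags.tolist() == [True, False]

    def test_linearity_in_dosages(self):
        rng = np.random.default_rng(0)
        d1 = rng.integers(0, 3, size=(40, 2)).astype(float)
        d2 = rng.integers(0, 2, size=(40, 2)).astype(float)
        s1, _ = compute_prs(_two_variant_panel(d1), MODEL)
        s2, _ = compute_prs(_two_variant_panel(d2), MODEL)
        s12, _ = compute_prs(_two_variant_panel(d1 + d2), MODEL)
        assert np.allclose(s12, s1 + s2)

    def test_score_bounds_for_risk_only_weights(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(100, 2)).astype(float)
        scores, _ = compute_prs(_two_variant_panel(d), MODEL)
        assert scores.min() >= 0
        assert scores.max() <= 2 * sum(MODEL.weights) + 1e-12

    def test_absent_variant_rejected(self):
        panel = _two_variant_panel([[0, 0]])
        bad = PrsModel.from_odds_ratios([VariantKey("9", 9, "A", "G")], [2.0])
        with pytest.raises(KeyError):
            compute_prs(panel, bad)


class TestQuartileSummary:
    def test_top_quarter_all_cases(self):
        scores = np.arange(1, 9, dtype=float)
        pheno = np.array([0, 0, 0, 0, 0, 0, 1, 1])
        f_case, f_ctrl, flag = prs_quartile_summary(scores, pheno)
        assert (f_case, f_ctrl, flag) == (1.0, 0.0, False)

    def test_constant_scores_degenerate(self):
        f_case, f_ctrl, flag = prs_quartile_summary(np.ones(8),
                                                    np.array([1, 1, 0, 0] * 2))
        assert (f_case, f_ctrl, flag) == (0.0, 0.0, True)

    def test_tie_at_cut_counts_below(self):
        scores = np.array([0.0, 0.0, 0.0, 1.0])
        pheno = np.array([0, 0, 1, 1])
        f_case, f_ctrl, _ = prs_quartile_summary(scores, pheno)
        # cut is the 75th percentile (0.25); only the 1.0 sits above it
        assert f_case == 0.5 and f_ctrl == 0.0

    def test_cases_overrepresented_under_risk_model(self):
        hits = 0
        for rep in range(60):
            panel = simulate_cohort(CohortSimSpec(
                n_cases=150, n_controls=450,
                variants=(VariantSimSpec(maf=0.1, odds_ratio=2.2, position=1),
                          VariantSimSpec(maf=0.15, odds_ratio=1.64, position=2)),
                rng_seed=1000 + rep))
            model = PrsModel.from_odds_ratios(panel.variants, [2.2, 1.64])
            scores, _ = compute_prs(panel, model)
            f_case, f_ctrl, _ = prs_quartile_summary(scores, panel.phenotype)
            hits += f_case >= f_ctrl
        assert hits >= 0.95 * 60


class TestPrsAssociation:
    def test_single_variant_matches_sva_odds_ratio(self, risk_panel):
        """exp(PRS coefficient) equals the SVA OR after weight rescaling."""
        sva = logistic_sva(risk_panel, AnalysisConfig())[0]
        one = PrsModel.from_odds_ratios([risk_panel.variants[0]], [2.2])
        scores, _ = compute_prs(risk_panel, one)
        tab = prs_association(risk_panel, scores, covariates=())
        # score = ln(2.2) * dosage, so beta_prs = beta_dosage / ln(2.2)
        assert tab.loc["PRS", "Estimate"] * np.log(2.2) == pytest.approx(
            sva.beta, abs=1e-6)

    def test_term_rows_and_adjustments(self, risk_panel):
        scores, _ = compute_prs(risk_panel, PrsModel.from_odds_ratios(
            list(risk_panel.variants), [2.2, 1.64]))
        tab = prs_association(risk_panel, scores)
        assert "PRS" in tab.index and "AGE" in tab.index
        m = len(tab)
        assert np.allclose(tab["Bonf"], np.minimum(tab["P"] * m, 1.0))
        assert (tab["FDR"] <= tab["Bonf"] + 1e-12).all()
        assert (tab.loc["PRS", "2.5%"] <= tab.loc["PRS", "OR"]
                <= tab.loc["PRS", "97.5%"])

    def test_constant_score_rejected(self, risk_panel):
        with pytest.raises(ValueError):
            prs_association(risk_panel, np.zeros(len(risk_panel.samples)))

    def test_permuted_phenotype_calibration(self, risk_panel):
        scores, _ = compute_prs(risk_panel, PrsModel.from_odds_ratios(
            list(risk_panel.variants), [2.2, 1.64]))
        rng = np.random.default_rng(9)
        rejections = 0
        n_perm = 200
        for _ in range(n_perm):
            shuffled = GenotypePanel(
                samples=risk_panel.samples,
                variants=risk_panel.variants,
                dosages=risk_panel.dosages,
                phenotype=rng.permutation(risk_panel.phenotype),
                covariates=risk_panel.covariates)
            tab = prs_association(shuffled, scores, covariates=())
            rejections += tab.loc["PRS", "P"] < 0.05
        assert 0.01 <= rejections / n_perm <= 0.10
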