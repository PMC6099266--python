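import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import grsmr
from grsmr import AnalysisSpec, FitError, SimulationConfig, VariantWeight
from grsmr.estimation import _design_matrix, _fit_logistic_irls


@pytest.fixture(scope="module")
def fixture_scores(fixture_cohort, weights):
    return grsmr.compute_relative_exposure(fixture_cohort, weights)


class TestLogisticFit:
    def test_matches_statsmodels(self, fixture_cohort, fixture_scores):
        """The in-module Newton solver agrees with statsmodels Logit."""
        spec = AnalysisSpec()
        X, y, _ = _design_matrix(fixture_cohort, fixture_scores.score,
                                 spec.resolve_covariates(fixture_cohort))
        beta, cov = _fit_logistic_irls(X, y)
        ref = sm.Logit(y.astype(float), X).fit(disp=0, method="newton")
        np.testing.assert_allclose(beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(cov)), ref.bse, atol=1e-6)

    def test_recovers_large_effect(self, weights):
        """theta = log 2 at n = 20,000 without confounding is recovered."""
        cfg = SimulationConfig(
            strata={"Europe": (9000, 11000)}, causal_log_or=np.log(2.0),
            confounder_effects={}, n_pcs=2, seed=101)
        cohort = grsmr.simulate_cohort(cfg)
        scores = grsmr.compute_relative_exposure(cohort, weights)
        est = grsmr.fit_causal_logistic(cohort, scores, AnalysisSpec())
        assert 1.8 <= est.odds_ratio <= 2.2

    def test_constant_score_is_error(self, fixture_cohort, fixture_scores):
        flat = grsmr.RelativeExposure(
            ids=fixture_scores.ids, score=np.ones_like(fixture_scores.score))
        with pytest.raises(FitError, match="zero variance"):
            grsmr.fit_causal_logistic(fixture_cohort, flat, AnalysisSpec())

    def test_needs_cases_and_controls(self, fixture_cohort, fixture_scores):
        controls = fixture_cohort.subset(~fixture_cohort.phenotypes["case"])
        with pytest.raises(FitError, match="at least one case"):
            grsmr.fit_causal_logistic(
                controls,
                grsmr.RelativeExposure(
                    ids=controls.phenotypes.index,
                    score=fixture_scores.as_series().reindex(
                        controls.phenotypes.index).to_numpy()),
                AnalysisSpec())

    def test_separation_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        X = np.column_stack([np.ones(200), x])
        y = x > 0  # perfectly separated
        with pytest.raises(FitError, match="separation"):
            _fit_logistic_irls(X, y)

    def test_affine_covariate_recoding_leaves_estimate_unchanged(
            self, fixture_cohort, fixture_scores):
        spec = AnalysisSpec()
        base = grsmr.fit_causal_logistic(fixture_cohort, fixture_scores, spec)
        shifted = grsmr.Cohort(fixture_cohort.dosages.copy(),
                               fixture_cohort.phenotypes.copy())
        shifted.phenotypes["pc1"] = 3.0 * shifted.phenotypes["pc1"] + 5.0
        alt = grsmr.fit_causal_logistic(shifted, fixture_scores, spec)
        assert alt.log_or == pytest.approx(base.log_or, abs=1e-7)
        assert alt.se_naive == pytest.approx(base.se_naive, abs=1e-7)


class TestBootstrapCorrection:
    def test_corrected_se_dominates_and_is_deterministic(
            self, fixture_cohort, weights):
        spec = AnalysisSpec(bootstrap_reps=200, seed=42)
        a = grsmr.bootstrap_weight_correction(fixture_cohort, weights, spec)
        b = grsmr.bootstrap_weight_correction(fixture_cohort, weights, spec)
        assert a.se_corrected >= a.se_naive
        assert a.se_corrected == b.se_corrected  # bit-identical under one seed
        assert a.log_or == b.log_or

    def test_point_estimate_is_original_weight_fit(self, fixture_cohort,
                                                   weights, fixture_scores):
        spec = AnalysisSpec(bootstrap_reps=50, seed=1)
        boot = grsmr.bootstrap_weight_correction(fixture_cohort, weights, spec)
        plain = grsmr.fit_causal_logistic(fixture_cohort, fixture_scores, spec)
        assert boot.log_or == pytest.approx(plain.log_or, abs=1e-9)
        assert boot.se_naive == pytest.approx(plain.se_naive, abs=1e-9)

    def test_negligible_weight_uncertainty_degenerates_to_naive(
            self, fixture_cohort, weights):
        tight = [
            VariantWeight(rsid=w.rsid, chrom=w.chrom, pos=w.pos,
                          effect_allele=w.effect_allele,
                          other_allele=w.other_allele, eaf=w.eaf,
                          beta=w.beta, se=1e-15, pvalue=w.pvalue)
            for w in weights
        ]
        spec = AnalysisSpec(bootstrap_reps=20, seed=5)
        est = grsmr.bootstrap_weight_correction(fixture_cohort, tight, spec)
        assert est.se_corrected == est.se_naive

    def test_large_b_stabilizes(self, fixture_cohort, weights):
        """Two independent B=2000 runs differ by under 1%."""
        a = grsmr.bootstrap_weight_correction(
            fixture_cohort, weights, AnalysisSpec(bootstrap_reps=2000, seed=1))
        b = grsmr.bootstrap_weight_correction(
            fixture_cohort, weights, AnalysisSpec(bootstrap_reps=2000, seed=2))
        assert abs(a.se_corrected - b.se_corrected) / a.se_corrected < 0.01

    def test_minimum_replicates_enforced(self):
        with pytest.raises(grsmr.ValidationError, match="at least 2"):
            AnalysisSpec(bootstrap_reps=1)


class TestStratifiedEstimates:
    def test_one_estimate_per_stratum_per_site(self, fixture_cohort,
                                               weights, fixture_scores):
        for site in ("oral", "oropharyngeal", "combined"):
            ests = grsmr.estimate_all_strata(
                fixture_cohort, fixture_scores, AnalysisSpec(site_filter=site))
            assert [e.label.split("/")[1] for e in ests] == \
                ["Europe", "North America", "South America"]

    def test_single_stratum_equals_whole_cohort_fit(self, weights):
        cfg = SimulationConfig(strata={"Europe": (400, 500)}, n_pcs=3, seed=2)
        cohort = grsmr.simulate_cohort(cfg)
        scores = grsmr.compute_relative_exposure(cohort, weights)
        spec = AnalysisSpec()
        (only,) = grsmr.estimate_all_strata(cohort, scores, spec)
        full = grsmr.fit_causal_logistic(cohort, scores, spec)
        assert only.log_or == pytest.approx(full.log_or, abs=1e-12)

    def test_structured_stratum_inflated(self, weights):
        """The hidden-subpopulation stratum shows an elevated OR."""
        hits = 0
        for seed in range(5):
            cfg = SimulationConfig(
                strata={"Europe": (600, 700), "North America": (550, 600),
                        "South America": (300, 350)},
                structure_scenario=True, n_pcs=2, seed=1000 + seed)
            cohort = grsmr.simulate_cohort(cfg)
            scores = grsmr.compute_relative_exposure(cohort, weights)
            ests = grsmr.estimate_all_strata(cohort, scores, AnalysisSpec())
            by = {e.label.split("/")[1]: e.log_or for e in ests}
            if by["South America"] > max(by["Europe"], by["North America"]):
                hits += 1
        assert hits == 5
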