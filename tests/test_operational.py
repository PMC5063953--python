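"""Operational-model fitting: recovery, ratio identity, error propagation."""

import numpy as np
import pytest

import gpcrbias as g
from gpcrbias.synthetic import ExpressionMeasurement

from conftest import curves_for


class TestRecovery:
    def test_noiseless_recovery_anchored_system_max(self, wt_camp_noiseless):
        ops = g.fit_operational(wt_camp_noiseless, em=100.0)
        assert ops["GLP-1"].log_tau == pytest.approx(1.22, abs=1e-4)
        assert ops["GLP-1"].log_KA == pytest.approx(-8.35, abs=1e-4)
        assert ops["exendin-4"].log_tau == pytest.approx(1.33, abs=1e-4)
        assert ops["oxyntomodulin"].log_KA == pytest.approx(-7.44, abs=1e-4)

    def test_noiseless_recovery_free_system_max_nonunit_slope(self):
        # a non-unit transducer slope makes E_m identifiable without anchor
        truths = [g.GroundTruth(ligand="a", log_tau=0.8, log_KA=-8.0, slope_n=1.5),
                  g.GroundTruth(ligand="b", log_tau=-0.3, log_KA=-7.0, slope_n=1.5)]
        ops = g.fit_operational(curves_for(truths))
        assert ops["a"].log_tau == pytest.approx(0.8, abs=1e-3)
        assert ops["a"].slope_n == pytest.approx(1.5, abs=1e-3)
        assert ops["b"].log_KA == pytest.approx(-7.0, abs=1e-3)

    def test_zero_efficacy_curve_flagged_nd(self):
        truths = [g.GroundTruth(ligand="dead", log_tau=-9.0, log_KA=-8.0)]
        curves = curves_for(truths, noise_sd=0.0)
        ops = g.fit_operational(curves, em=100.0, noise_sd_est=1.0)
        assert ops["dead"].nd

    def test_too_few_concentrations_rejected(self):
        truths = [g.GroundTruth(ligand="a")]
        curves = curves_for(truths, n_conc=4)
        # 4 distinct concentrations cannot constrain 5+ free parameters
        with pytest.raises(ValueError):
            g.fit_operational(curves)


class TestRatioParameterization:
    def test_identity_with_composed_ratio_noiseless(self, wt_camp_noiseless):
        ops = g.fit_operational(wt_camp_noiseless, em=100.0)
        rats = g.fit_transduction_ratio(wt_camp_noiseless, em=100.0)
        for lig in rats:
            assert rats[lig].log_ratio == pytest.approx(
                ops[lig].log_ratio, abs=1e-4)

    def test_direct_ratio_se_not_worse_than_naive_combination(self):
        # at unit slope the (log tau, log K_A) estimates of a partial
        # agonist are positively correlated, so the direct-ratio SE beats
        # the naive uncorrelated quadrature and equals the covariance-aware
        # composition
        truths = [g.GroundTruth(ligand="partial", log_tau=np.log10(0.5),
                                log_KA=-7.5)]
        curves = curves_for(truths, noise_sd=5.0, n_experiments=5, seed=9)
        ops = g.fit_operational(curves, em=100.0, slope_mode="fixed1")
        rats = g.fit_transduction_ratio(curves, em=100.0, slope_mode="fixed1")
        o = ops["partial"]
        naive = np.hypot(o.log_tau_se, o.log_KA_se)
        assert rats["partial"].log_ratio_se <= naive * 1.001
        assert rats["partial"].log_ratio_se == pytest.approx(
            o.log_ratio_se, rel=0.05)

    def test_wildtype_like_ratio_value(self, wt_camp_noiseless):
        rats = g.fit_transduction_ratio(wt_camp_noiseless, em=100.0)
        assert rats["GLP-1"].log_ratio == pytest.approx(1.22 + 8.35, abs=1e-3)

    def test_ratio_invariant_to_response_rescaling(self):
        truths = [g.GroundTruth(ligand="a", log_tau=0.5, log_KA=-8.0)]
        curves = curves_for(truths)
        r1 = g.fit_transduction_ratio(curves, em=100.0)["a"].log_ratio
        scaled = [g.ResponseCurve(c.receptor, c.ligand, c.pathway, c.conc,
                                  c.response * 2.5, c.experiment)
                  for c in curves]
        r2 = g.fit_transduction_ratio(scaled, em=250.0)["a"].log_ratio
        assert r2 == pytest.approx(r1, abs=1e-6)

    def test_monte_carlo_accuracy_and_coverage(self, wt_camp_truth):
        # study-like design: 3 ligands, 5 experiments, 5% noise
        errs, covered = [], 0
        n_rep = 150
        for s in range(n_rep):
            curves = curves_for(wt_camp_truth, noise_sd=5.0,
                                n_experiments=5, seed=1000 + s)
            rats = g.fit_transduction_ratio(curves, em=100.0)
            r = rats["GLP-1"]
            err = r.log_ratio - (1.22 + 8.35)
            errs.append(abs(err))
            if abs(err) <= 1.96 * r.log_ratio_se:
                covered += 1
        assert np.median(errs) < 0.1
        assert 0.90 <= covered / n_rep <= 0.99


class TestExpressionCorrection:
    def test_full_expression_is_identity(self):
        expr = ExpressionMeasurement(100.0, 0.0, 5)
        v, s = g.correct_to_expression(1.0, 0.1, expr)
        assert v == 1.0 and s == 0.1

    def test_half_expression_adds_log2(self):
        expr = ExpressionMeasurement(50.0, 0.0, 5)
        v, s = g.correct_to_expression(1.0, 0.1, expr)
        assert v == pytest.approx(1.301, abs=1e-3)
        assert s == pytest.approx(0.1)

    def test_correction_composes_to_identity(self):
        half = ExpressionMeasurement(50.0, 0.0, 5)
        double = ExpressionMeasurement(200.0, 0.0, 5)
        v1, _ = g.correct_to_expression(0.7, 0.05, half)
        v2, _ = g.correct_to_expression(v1, 0.05, double)
        assert v2 == pytest.approx(0.7, abs=1e-12)

    def test_propagated_se_matches_monte_carlo(self):
        # delta-method SE vs 10^5 draws through the same transform
        rng = np.random.default_rng(17)
        log_tau, se_tau = 1.0, 0.1
        pct, sem = 60.0, 4.0
        expr = ExpressionMeasurement(pct, sem, 5)
        _, prop = g.correct_to_expression(log_tau, se_tau, expr)
        draws = (rng.normal(log_tau, se_tau, 100_000)
                 + np.log10(100.0 / rng.normal(pct, sem, 100_000)))
        assert prop == pytest.approx(draws.std(ddof=1), rel=0.03)
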