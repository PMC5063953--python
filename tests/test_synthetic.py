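"""Synthetic-data generator: forward models, noise contract, reproducibility."""

import numpy as np
import pytest

import gpcrbias as g
from gpcrbias.synthetic import operational_response, competition_response


class TestResponseCurveSimulation:
    def test_noiseless_matches_closed_form(self):
        truth = g.GroundTruth(log_tau=1.22, log_KA=-8.35)
        design = g.AssayDesign(g.default_concentrations(9.0), noise_sd=0.0,
                               n_experiments=1)
        curve = g.simulate_response_curve(truth, design)
        expected = operational_response(design.concentrations, 1.22, -8.35)
        np.testing.assert_allclose(curve.response, expected, rtol=1e-12)

    def test_saturating_limit_of_strong_agonist(self):
        # at A -> inf the operational response tends to E_m tau/(1+tau)
        limit = operational_response(1.0, 1.22, -8.35)  # 1 M is >> K_A
        tau = 10 ** 1.22
        assert limit == pytest.approx(100 * tau / (1 + tau), abs=1e-3)
        assert limit == pytest.approx(94.3, abs=0.05)

    def test_zero_efficacy_gives_flat_basal(self):
        truth = g.GroundTruth(log_tau=-12.0, log_KA=-8.0, basal=3.0)
        design = g.AssayDesign(g.default_concentrations(8.0), noise_sd=0.0)
        curve = g.simulate_response_curve(truth, design)
        np.testing.assert_allclose(curve.response, 3.0, atol=1e-6)

    def test_nan_tau_simulates_signal_free_curve(self):
        truth = g.GroundTruth(log_tau=np.nan, log_KA=-8.0)
        design = g.AssayDesign(g.default_concentrations(8.0), noise_sd=0.0)
        curve = g.simulate_response_curve(truth, design)
        np.testing.assert_allclose(curve.response, 0.0, atol=1e-12)

    def test_noise_sd_contract_monte_carlo(self):
        # empirical SD over 10^4 independent draws at one concentration
        truth = g.GroundTruth()
        design = g.AssayDesign(np.array([1e-8]), n_experiments=10_000,
                               noise_sd=5.0, seed=11)
        curve = g.simulate_response_curve(truth, design)
        assert curve.response.std(ddof=1) == pytest.approx(5.0, rel=0.02)

    def test_reproducible_and_label_independent_streams(self):
        design = g.AssayDesign(g.default_concentrations(8.5), noise_sd=5.0, seed=3)
        a1 = g.simulate_response_curve(g.GroundTruth(ligand="GLP-1"), design)
        a2 = g.simulate_response_curve(g.GroundTruth(ligand="GLP-1"), design)
        b = g.simulate_response_curve(g.GroundTruth(ligand="exendin-4"), design)
        np.testing.assert_array_equal(a1.response, a2.response)
        assert not np.allclose(a1.response, b.response)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            g.AssayDesign(np.array([]))

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            g.AssayDesign(np.array([1e-7, 1e-8]))


class TestCompetitionBinding:
    def test_no_competitor_and_ic50_points(self):
        assert competition_response(0.0, 8.0, 0.05e-9, 8.11) == 100.0
        ic50 = 10 ** -8.0 * (1 + 0.05e-9 / 10 ** -8.11)
        assert competition_response(ic50, 8.0, 0.05e-9, 8.11) == pytest.approx(50.0)

    def test_tracer_occupancy_ratio(self):
        # IC50/Ki at 0.05 nM tracer against K_d = 10^-8.11 M
        ratio = (1 + 0.05e-9 / 10 ** -8.11)
        assert ratio == pytest.approx(1.0064, abs=1e-3)

    def test_nonpositive_tracer_rejected(self):
        design = g.AssayDesign(g.default_concentrations(8.0))
        with pytest.raises(ValueError):
            g.simulate_competition_binding(8.0, 0.0, 8.11, design)


class TestExpression:
    def test_zero_cv_is_exact(self):
        m = g.simulate_expression(100.0, 0.0, 5, seed=0)
        assert m.elisa_pct == 100.0 and m.elisa_sem == 0.0

    @pytest.mark.parametrize("truth", [100.0, 39.0])
    def test_large_n_mean_converges(self, truth):
        m = g.simulate_expression(truth, 0.05, 10_000, seed=5)
        assert m.elisa_pct == pytest.approx(truth, rel=0.01)

    def test_positivity(self):
        m = g.simulate_expression(5.0, 1.0, 1000, seed=2)
        assert m.elisa_pct > 0


class TestPanel:
    def test_panel_is_deterministic(self):
        p1 = g.simulate_panel(seed=4)
        p2 = g.simulate_panel(seed=4)
        for key in ("functional", "binding", "expression"):
            np.testing.assert_array_equal(
                p1[key].to_numpy(), p2[key].to_numpy())

    def test_panel_covers_design(self):
        p = g.simulate_panel(seed=0)
        f = p["functional"]
        assert set(f["pathway"]) == {"cAMP", "pERK", "iCa"}
        assert f["receptor"].nunique() == 13
        # binding includes the antagonist
        assert "exendin-4(9-39)" in set(p["binding"]["ligand"])

    def test_nd_truth_rows_become_flat_curves(self):
        p = g.simulate_panel(seed=0, noise_sd=0.0)
        f = p["functional"]
        flat = f[(f.receptor == "N2.52A") & (f.pathway == "iCa")]
        assert np.allclose(flat["response"], 0.0)
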