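"""Bias quantification: wildtype normalization, bias factors, sentinels."""

import numpy as np
import pytest

import gpcrbias as g
from gpcrbias.operational import TransductionCoefficient as TC
from gpcrbias.bias import DeltaLogR


def tc(receptor="mut", ligand="GLP-1", pathway="cAMP", log_r=9.0, se=0.1,
       nd=False):
    return TC(receptor, ligand, pathway, log_r=log_r, log_r_se=se, nd=nd)


class TestDeltaLogR:
    def test_identical_inputs_are_zero(self):
        wt = tc("wildtype")
        d = g.delta_log_r(wt, wt)
        assert d.value == 0.0
        assert d.se == pytest.approx(np.sqrt(2) * 0.1)

    def test_quadrature_arithmetic(self):
        d = g.delta_log_r(tc(log_r=8.5, se=0.2), tc("wildtype", log_r=9.5, se=0.1))
        assert d.value == pytest.approx(-1.0)
        assert d.se == pytest.approx(0.224, abs=1e-3)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            g.delta_log_r(tc(pathway="cAMP"), tc("wildtype", pathway="pERK"))

    def test_nd_propagates(self):
        d = g.delta_log_r(tc(nd=True), tc("wildtype"))
        assert d.nd and np.isnan(d.value)


def dlr(pathway, value=0.0, se=0.1, nd=False, receptor="mut", ligand="GLP-1"):
    return DeltaLogR(receptor, ligand, pathway, value=value, se=se, nd=nd)


class TestBiasFactor:
    def test_equal_deltas_give_unity(self):
        b = g.bias_factor(dlr("pERK", 0.4), dlr("cAMP", 0.4))
        assert b.ddlog_r == pytest.approx(0.0)
        assert b.linear == pytest.approx(1.0)

    def test_antisymmetry_under_pathway_swap(self):
        b12 = g.bias_factor(dlr("pERK", 0.9, 0.2), dlr("iCa", -0.48, 0.3))
        b21 = g.bias_factor(dlr("iCa", -0.48, 0.3), dlr("pERK", 0.9, 0.2))
        assert b12.ddlog_r == pytest.approx(-b21.ddlog_r)
        assert b12.linear * b21.linear == pytest.approx(1.0)
        assert b12.se == pytest.approx(b21.se)

    def test_triangle_identity_exact(self):
        d1, d2, d3 = dlr("pERK", 0.7, 0.1), dlr("cAMP", -0.2, 0.2), dlr("iCa", 0.3, 0.15)
        lhs = g.bias_factor(d1, d3).ddlog_r
        rhs = g.bias_factor(d1, d2).ddlog_r + g.bias_factor(d2, d3).ddlog_r
        # algebraically exact (differences of the same terms); tolerance
        # only covers float non-associativity
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_sentinel_directions(self):
        b = g.bias_factor(dlr("pERK", 0.5), dlr("iCa", nd=True))
        assert b.sentinel == +1 and b.presentation_value() == 100.0
        b = g.bias_factor(dlr("pERK", nd=True), dlr("iCa", 0.5))
        assert b.sentinel == -1 and b.presentation_value() == -100.0
        assert b.nd and np.isnan(b.ddlog_r)  # sentinel rows are non-numeric

    def test_both_nd_is_undefined_without_sentinel(self):
        b = g.bias_factor(dlr("pERK", nd=True), dlr("iCa", nd=True))
        assert b.sentinel == 0 and b.nd

    def test_same_pathway_rejected(self):
        with pytest.raises(ValueError):
            g.bias_factor(dlr("pERK"), dlr("pERK"))

    def test_mismatched_ligand_rejected(self):
        with pytest.raises(ValueError):
            g.bias_factor(dlr("pERK", ligand="GLP-1"),
                          dlr("iCa", ligand="exendin-4"))

    def test_propagated_se_matches_monte_carlo(self):
        rng = np.random.default_rng(23)
        # two-stage propagation: (mut - wt) per pathway, then difference
        se_m1, se_w1, se_m2, se_w2 = 0.12, 0.08, 0.2, 0.05
        d1 = g.delta_log_r(tc(log_r=9.0, se=se_m1, pathway="pERK"),
                           tc("wildtype", log_r=8.0, se=se_w1, pathway="pERK"))
        d2 = g.delta_log_r(tc(log_r=7.0, se=se_m2, pathway="iCa"),
                           tc("wildtype", log_r=7.5, se=se_w2, pathway="iCa"))
        b = g.bias_factor(d1, d2)
        n = 100_000
        draws = ((rng.normal(9.0, se_m1, n) - rng.normal(8.0, se_w1, n))
                 - (rng.normal(7.0, se_m2, n) - rng.normal(7.5, se_w2, n)))
        assert b.se == pytest.approx(draws.std(ddof=1), rel=0.03)


class TestSignificance:
    def test_null_distribution_not_significant(self):
        rng = np.random.default_rng(3)
        groups = {"wildtype": rng.normal(0, 0.2, 5),
                  "mut": rng.normal(0, 0.2, 5)}
        flags = g.flag_significance(groups, "wildtype")
        assert flags == {"mut": False}

    def test_large_effect_significant(self):
        groups = {"wildtype": g.replicates_from_summary(0.0, 0.2, 5),
                  "mut": g.replicates_from_summary(1.5, 0.2, 5)}
        flags = g.flag_significance(groups, "wildtype")
        assert flags == {"mut": True}
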