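"""Three-parameter logistic fitting: recovery, equivariances, ND rules."""

import numpy as np
import pytest

import gpcrbias as g
from gpcrbias.dose_response import ResponseCurve, LogisticFit, logistic3

from conftest import curves_for


def logistic_curve(pEC50, Emax=100.0, basal=0.0, center=None, noise=None,
                   n_exp=1, seed=0, **labels):
    center = pEC50 if center is None else center
    conc = g.default_concentrations(center)
    rng = np.random.default_rng(seed)
    concs, resps, exps = [], [], []
    for e in range(n_exp):
        y = logistic3(conc, pEC50, Emax, basal)
        if noise:
            y = y + rng.normal(0, noise, size=conc.size)
        concs.append(conc); resps.append(y); exps.append(np.full(conc.size, e))
    return ResponseCurve(labels.get("receptor", "wildtype"),
                         labels.get("ligand", "GLP-1"),
                         labels.get("pathway", "cAMP"),
                         np.concatenate(concs), np.concatenate(resps),
                         np.concatenate(exps))


class TestRecovery:
    def test_noiseless_recovery_machine_tolerance(self):
        fit = g.fit_logistic3(logistic_curve(9.84))
        assert fit.pEC50 == pytest.approx(9.84, abs=1e-6)
        assert fit.Emax == pytest.approx(100.0, abs=1e-6)
        assert fit.basal == pytest.approx(0.0, abs=1e-6)
        assert not fit.nd

    def test_monte_carlo_calibration(self):
        # 500 noisy curves: mean fitted pEC50 within 0.05 of truth and
        # the fit SE magnitude agrees with the empirical scatter
        fits = [g.fit_logistic3(logistic_curve(8.0, noise=5.0, n_exp=6, seed=s))
                for s in range(500)]
        p = np.array([f.pEC50 for f in fits])
        se = np.array([f.pEC50_se for f in fits])
        assert p.mean() == pytest.approx(8.0, abs=0.05)
        assert 0.5 < p.std() / se.mean() < 2.0

    def test_operational_limit_ec50_equals_ka_over_one_plus_tau(self, wt_camp_noiseless):
        # with unit slope the operational curve is exactly a logistic with
        # EC50 = K_A/(1+tau)
        for curve, (lt, lka) in zip(wt_camp_noiseless,
                                    [(1.22, -8.35), (0.92, -7.44), (1.33, -9.24)]):
            fit = g.fit_logistic3(curve)
            expected = -np.log10(10 ** lka / (1 + 10 ** lt))
            assert fit.pEC50 == pytest.approx(expected, abs=1e-6)


class TestEquivariance:
    def test_response_scale(self):
        c = logistic_curve(8.5, noise=2.0, n_exp=3, seed=1)
        f1 = g.fit_logistic3(c)
        c2 = ResponseCurve(c.receptor, c.ligand, c.pathway, c.conc,
                           c.response * 3.0, c.experiment)
        f2 = g.fit_logistic3(c2)
        assert f2.pEC50 == pytest.approx(f1.pEC50, abs=1e-6)
        assert f2.Emax == pytest.approx(3 * f1.Emax, rel=1e-6)
        assert f2.basal == pytest.approx(3 * f1.basal, abs=1e-5)

    def test_concentration_unit_shift(self):
        c = logistic_curve(8.5, noise=2.0, n_exp=3, seed=1)
        f1 = g.fit_logistic3(c)
        c2 = ResponseCurve(c.receptor, c.ligand, c.pathway, c.conc * 1e-9,
                           c.response, c.experiment)
        f2 = g.fit_logistic3(c2)
        assert f2.pEC50 - f1.pEC50 == pytest.approx(9.0, abs=1e-6)


class TestNDRules:
    def test_flat_curve_is_nd(self):
        conc = g.default_concentrations(8.0)
        c = ResponseCurve("m", "l", "p", conc, np.zeros(conc.size))
        fit = g.fit_logistic3(c, noise_sd_est=5.0)
        assert fit.nd

    def test_span_threshold(self):
        fit = LogisticFit(pEC50=8.0, Emax=2.0, basal=0.0, converged=True)
        assert g.flag_nd(fit, noise_sd_est=5.0)
        fit = LogisticFit(pEC50=8.0, Emax=90.0, basal=0.0, converged=True)
        assert not g.flag_nd(fit, noise_sd_est=5.0,
                             conc_range=(1e-10, 1e-6))

    def test_midpoint_outside_range_is_nd(self):
        fit = LogisticFit(pEC50=12.0, Emax=90.0, basal=0.0, converged=True)
        assert g.flag_nd(fit, conc_range=(1e-10, 1e-6))

    def test_too_few_concentrations_rejected(self):
        conc = np.array([1e-7, 1e-6])
        c = ResponseCurve("m", "l", "p", conc, np.array([80.0, 95.0]))
        with pytest.raises(ValueError, match="distinct concentrations"):
            g.fit_logistic3(c)

    def test_degenerate_identical_concentrations_hard_error(self):
        c = ResponseCurve("m", "l", "p", np.full(6, 1e-8),
                          np.linspace(0, 90, 6))
        with pytest.raises(ValueError):
            g.fit_logistic3(c)
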