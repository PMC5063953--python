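"""Operational-model (Black-Leff) efficacy analysis.

The operational model of agonism separates what a ligand does to a
receptor into affinity and efficacy:

    E(A) = basal + (E_m - basal) * tau^n A^n / (tau^n A^n + (A + K_A)^n)

where ``tau`` is the operational efficacy (coupling of the agonist-bound
receptor to one pathway, proportional to receptor density), ``K_A`` the
functional (molar) affinity of the agonist for the receptor state coupled
to that pathway, ``E_m`` the maximal response of the system, and ``n`` the
transducer slope. Curves for all ligands at one receptor x pathway are fit
globally: ``E_m``, ``basal`` and ``n`` are shared, while ``log10 tau`` and
``log10 K_A`` are free per ligand. Magnitude parameters are estimated on
the log10 scale, where their sampling errors are approximately normal.

A reparameterized variant estimates the transduction coefficient
``R = tau/K_A`` directly,

    E(A) = basal + (E_m - basal) * (R A)^n / ((R A)^n + (1 + A/K_A)^n),

so the standard error of ``log10 R`` comes straight from the fit
covariance instead of combining two strongly correlated estimates.

Identifiability note: with ``n = 1`` each ligand's curve is exactly a
logistic with apparent maximum ``E_m tau/(1+tau)`` and EC50
``K_A/(1+tau)`` — *any* ``E_m`` at or above the observed plateaus can fit
such data perfectly, so ``E_m`` cannot be estimated from agonist curves
alone. When the response scale is anchored to a system-maximal control
(responses in % of e.g. a forskolin maximum), pass ``em=100`` to pin the
system maximum; otherwise ``E_m`` is fitted shared across ligands and the
near-degeneracy surfaces as a wide-SE flag on ``log K_A``.

Efficacies are made comparable across constructs with different surface
expression by the correction ``log tau_c = log tau + log10(100/expr%)``,
with the expression uncertainty propagated by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .dose_response import ResponseCurve, fit_logistic3, MIN_DISTINCT_CONC
from .synthetic import ExpressionMeasurement

__all__ = [
    "OperationalFit", "RatioFit", "TransductionCoefficient",
    "fit_operational", "fit_transduction_ratio", "correct_to_expression",
    "operational_ratio_response",
]

LN10 = np.log(10.0)

#: log10 K_A standard errors above this are reported as unidentifiable
#: (flat profile likelihood of a near-full agonist).
WIDE_SE_THRESHOLD = 2.0

SLOPE_BOUNDS = (0.5, 3.0)
LOG_TAU_BOUNDS = (-5.0, 5.0)
LOG_KA_BOUNDS = (-15.0, 0.0)
LOG_R_BOUNDS = (-5.0, 20.0)


@dataclass
class OperationalFit:
    """Per-ligand mechanistic descriptors from a global operational fit."""

    ligand: str = ""
    log_tau: float = np.nan
    log_tau_se: float = np.nan
    log_KA: float = np.nan  # log10 molar; -log_KA is the pK_A
    log_KA_se: float = np.nan
    E_m: float = np.nan
    E_m_se: float = np.nan
    slope_n: float = np.nan
    slope_n_se: float = np.nan
    basal: float = np.nan
    basal_se: float = np.nan
    #: 2x2 covariance of (log_tau, log_KA)
    cov_tau_ka: np.ndarray = field(default_factory=lambda: np.full((2, 2), np.nan))
    converged: bool = False
    nd: bool = False
    wide_se: bool = False

    @property
    def log_ratio(self) -> float:
        """Composed transduction coefficient log10(tau/K_A)."""
        return self.log_tau - self.log_KA

    @property
    def log_ratio_se(self) -> float:
        """SE of the composed ratio, using the full (log tau, log K_A)
        covariance: var = var_tau + var_KA - 2 cov."""
        v = self.cov_tau_ka
        return float(np.sqrt(max(v[0, 0] + v[1, 1] - 2 * v[0, 1], 0.0)))


@dataclass
class RatioFit:
    """Per-ligand directly-estimated transduction coefficient."""

    ligand: str = ""
    log_ratio: float = np.nan
    log_ratio_se: float = np.nan
    converged: bool = False
    nd: bool = False


@dataclass
class TransductionCoefficient:
    """Expression-corrected log10(tau_c/K_A) with propagated SE."""

    receptor: str
    ligand: str
    pathway: str
    log_r: float = np.nan
    log_r_se: float = np.nan
    log_tau_c: float = np.nan
    log_tau_c_se: float = np.nan
    nd: bool = False


def operational_ratio_response(conc, log_R, log_KA, E_m=100.0, basal=0.0, n=1.0):
    """Ratio-parameterized operational response (see module docstring)."""
    A = np.asarray(conc, dtype=float)
    R = 10.0 ** log_R
    KA = 10.0 ** log_KA
    num = (R * A) ** n
    return basal + (E_m - basal) * num / (num + (1.0 + A / KA) ** n)


def _prefits(curves, noise_sd_est):
    """Logistic prefits used for starting values and ND screening."""
    out = {}
    for c in curves:
        out[c.ligand] = fit_logistic3(c, noise_sd_est=noise_sd_est)
    return out


def _covariance(result, n_obs, n_par):
    """Asymptotic covariance from a least_squares result."""
    J = result.jac
    dof = max(n_obs - n_par, 1)
    s2 = 2.0 * result.cost / dof
    try:
        cov = np.linalg.inv(J.T @ J) * s2
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(J.T @ J) * s2
    return cov


def _check_identifiable(curves, n_par):
    n_obs = sum(c.conc.size for c in curves)
    n_conc = sum(c.n_distinct_conc for c in curves)
    if n_conc < n_par:
        raise ValueError(
            f"{n_conc} distinct concentrations cannot constrain {n_par} parameters")
    return n_obs


def _global_fit(curves, model, per_ligand_p0, per_ligand_bounds, *,
                em, slope_mode, basal0, em0):
    """Shared machinery for the two operational parameterizations.

    ``model(conc, p_lig, Em, basal, n)`` evaluates one ligand's curve from
    its 2-vector of per-ligand parameters. Returns (theta, cov, layout)
    where layout maps names to indices in theta.
    """
    ligands = [c.ligand for c in curves]
    fit_em = em is None
    fit_n = slope_mode == "estimated"

    idx = {}
    p0, lo, hi = [], [], []
    if fit_em:
        idx["E_m"] = len(p0)
        p0.append(em0); lo.append(1e-6); hi.append(np.inf)
    idx["basal"] = len(p0)
    p0.append(basal0); lo.append(-np.inf); hi.append(np.inf)
    if fit_n:
        idx["n"] = len(p0)
        p0.append(1.0); lo.append(SLOPE_BOUNDS[0]); hi.append(SLOPE_BOUNDS[1])
    for lig in ligands:
        idx[lig] = len(p0)
        (a0, b0), ((alo, ahi), (blo, bhi)) = per_ligand_p0[lig], per_ligand_bounds
        p0 += [np.clip(a0, alo, ahi), np.clip(b0, blo, bhi)]
        lo += [alo, blo]; hi += [ahi, bhi]

    def unpack(theta):
        Em = theta[idx["E_m"]] if fit_em else em
        basal = theta[idx["basal"]]
        n = theta[idx["n"]] if fit_n else 1.0
        return Em, basal, n

    def residuals(theta):
        Em, basal, n = unpack(theta)
        res = []
        for c in curves:
            j = idx[c.ligand]
            res.append(model(c.conc, theta[j], theta[j + 1], Em, basal, n)
                       - c.response)
        return np.concatenate(res)

    n_par = len(p0)
    n_obs = _check_identifiable(curves, n_par)
    result = least_squares(residuals, np.asarray(p0), bounds=(lo, hi),
                           xtol=1e-14, ftol=1e-14, gtol=1e-14)
    cov = _covariance(result, n_obs, n_par)
    return result, cov, idx, unpack


def fit_operational(curves: list[ResponseCurve], *, em: float | None = None,
                    slope_mode: str = "estimated",
                    noise_sd_est: float | None = None) -> dict[str, OperationalFit]:
    """Globally fit the operational model to all ligand curves of one
    receptor x pathway.

    ``E_m``, ``basal`` and (if ``slope_mode="estimated"``) the transducer
    slope ``n`` are shared across ligands; ``(log tau, log K_A)`` are free
    per ligand. ``em`` anchors the system maximum externally (see module
    docstring); ``slope_mode="fixed1"`` fixes ``n = 1``.

    Ligands whose logistic prefit is ND (no detectable response) are
    returned with ``nd=True`` and excluded from the global fit. The
    returned covariance of (log tau, log K_A) supports composing
    log(tau/K_A) with a correct SE.
    """
    if not curves:
        raise ValueError("need at least one curve")
    if slope_mode not in ("estimated", "fixed1"):
        raise ValueError(f"unknown slope_mode {slope_mode!r}")

    pre = _prefits(curves, noise_sd_est)
    live = [c for c in curves if not pre[c.ligand].nd]
    out = {c.ligand: OperationalFit(ligand=c.ligand, nd=True) for c in curves
           if pre[c.ligand].nd}
    if not live:
        return out

    basal0 = min(pre[c.ligand].basal for c in live)
    plateaus = {c.ligand: pre[c.ligand].Emax for c in live}
    em_eff = em if em is not None else None
    em0 = 1.10 * max(plateaus.values())

    p0 = {}
    anchor = em if em is not None else em0
    for c in live:
        lf = pre[c.ligand]
        frac = np.clip((lf.Emax - basal0) / max(anchor - basal0, 1e-9),
                       1e-3, 0.999)
        tau0 = frac / (1.0 - frac)
        ec50 = 10.0 ** (-lf.pEC50)
        p0[c.ligand] = (np.log10(tau0), np.log10(ec50 * (1.0 + tau0)))

    result, cov, idx, unpack = _global_fit(
        curves=live,
        model=lambda A, lt, lka, Em, basal, n: _op_model(A, lt, lka, Em, basal, n),
        per_ligand_p0=p0,
        per_ligand_bounds=(LOG_TAU_BOUNDS, LOG_KA_BOUNDS),
        em=em_eff, slope_mode=slope_mode, basal0=basal0, em0=em0)

    Em, basal, n = unpack(result.x)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    for c in live:
        j = idx[c.ligand]
        block = cov[np.ix_([j, j + 1], [j, j + 1])]
        fit = OperationalFit(
            ligand=c.ligand,
            log_tau=result.x[j], log_tau_se=se[j],
            log_KA=result.x[j + 1], log_KA_se=se[j + 1],
            E_m=Em, E_m_se=se[idx["E_m"]] if "E_m" in idx else 0.0,
            slope_n=n, slope_n_se=se[idx["n"]] if "n" in idx else 0.0,
            basal=basal, basal_se=se[idx["basal"]],
            cov_tau_ka=block,
            converged=result.success,
            wide_se=se[j + 1] > WIDE_SE_THRESHOLD)
        out[c.ligand] = fit
    return out


def _op_model(A, log_tau, log_KA, Em, basal, n):
    tau = 10.0 ** log_tau
    KA = 10.0 ** log_KA
    num = (tau * A) ** n
    return basal + (Em - basal) * num / (num + (A + KA) ** n)


def fit_transduction_ratio(curves: list[ResponseCurve], *,
                           em: float | None = None,
                           slope_mode: str = "estimated",
                           noise_sd_est: float | None = None) -> dict[str, RatioFit]:
    """Directly estimate log10(tau/K_A) per ligand (shared E_m, basal, n).

    Same global structure as :func:`fit_operational` but parameterized in
    the transduction coefficient, so its SE is read off the covariance
    rather than assembled from two correlated estimates.
    """
    if not curves:
        raise ValueError("need at least one curve")
    if slope_mode not in ("estimated", "fixed1"):
        raise ValueError(f"unknown slope_mode {slope_mode!r}")

    pre = _prefits(curves, noise_sd_est)
    live = [c for c in curves if not pre[c.ligand].nd]
    out = {c.ligand: RatioFit(ligand=c.ligand, nd=True) for c in curves
           if pre[c.ligand].nd}
    if not live:
        return out

    basal0 = min(pre[c.ligand].basal for c in live)
    em0 = 1.10 * max(pre[c.ligand].Emax for c in live)
    anchor = em if em is not None else em0
    p0 = {}
    for c in live:
        lf = pre[c.ligand]
        frac = np.clip((lf.Emax - basal0) / max(anchor - basal0, 1e-9),
                       1e-3, 0.999)
        tau0 = frac / (1.0 - frac)
        ka0 = 10.0 ** (-lf.pEC50) * (1.0 + tau0)
        p0[c.ligand] = (np.log10(tau0 / ka0), np.log10(ka0))

    result, cov, idx, unpack = _global_fit(
        curves=live,
        model=lambda A, lr, lka, Em, basal, n: operational_ratio_response(
            A, lr, lka, Em, basal, n),
        per_ligand_p0=p0,
        per_ligand_bounds=(LOG_R_BOUNDS, LOG_KA_BOUNDS),
        em=em, slope_mode=slope_mode, basal0=basal0, em0=em0)

    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    for c in live:
        j = idx[c.ligand]
        out[c.ligand] = RatioFit(ligand=c.ligand,
                                 log_ratio=result.x[j], log_ratio_se=se[j],
                                 converged=result.success)
    return out


def correct_to_expression(value: float, se: float,
                          expression: ExpressionMeasurement) -> tuple[float, float]:
    """Correct a log10 efficacy quantity to wildtype surface expression.

    ``value_c = value + log10(100/elisa%)``; the SE combines the fit SE and
    the delta-method SE of the log expression,
    ``SE(log10 X) = SEM(X)/(X ln 10)``, in quadrature. Applies equally to
    ``log tau`` (giving ``log tau_c``) and ``log(tau/K_A)`` (giving
    ``log(tau_c/K_A)``), since the correction is the same additive shift.
    """
    pct = expression.elisa_pct
    shift = np.log10(100.0 / pct)
    se_expr = expression.elisa_sem / (pct * LN10)
    return value + shift, float(np.sqrt(se ** 2 + se_expr ** 2))
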