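"""Synthetic assay data with known ground truth.

Generates the three data streams of a GPCR mutant-panel study:

* agonist concentration-response curves drawn from the operational model
  of agonism (the same forward model the fitting stage uses),
* whole-cell competition-binding curves (one-site competition against a
  fixed radiotracer concentration),
* cell-surface expression measurements (lognormal noise around a true
  %-of-wildtype level).

The replicate structure mirrors the emulated study design: four to six
independent experiments conducted in duplicate, with the mean of
duplicates treated as one observation. Noise is additive Gaussian on the
normalized response scale, homoscedastic across concentrations, because
responses are expressed as % of a system-maximal control and analysed
unweighted. Expression noise is lognormal so simulated expression stays
positive.

Reproducibility: every (receptor, ligand, pathway) curve draws from its
own pseudo-random stream derived from the master seed and the labels, so
adding one curve to a panel never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dose_response import ResponseCurve
from . import reference

__all__ = [
    "GroundTruth", "AssayDesign", "ExpressionMeasurement",
    "operational_response", "competition_response",
    "simulate_response_curve", "simulate_competition_binding",
    "simulate_expression", "simulate_panel", "default_concentrations",
    "DEFAULT_NOISE_SD", "DEFAULT_N_EXPERIMENTS",
]

#: Default per-observation noise SD in normalized-% units. Chosen so that
#: at 5 experiments the fitted pEC50 SEM lands in the 0.06-0.2 log-unit
#: range typical of this kind of panel.
DEFAULT_NOISE_SD = 5.0
DEFAULT_N_EXPERIMENTS = 5
DEFAULT_N_DUPLICATES = 2


@dataclass(frozen=True)
class GroundTruth:
    """True operational-model parameters for one receptor x ligand x pathway.

    ``log_tau`` is log10 of the operational efficacy; ``log_KA`` is log10
    of the molar functional affinity (i.e. the negative of pK_A); ``E_m``
    and ``basal`` are on the normalized % scale; ``expression_pct`` is cell
    surface expression as % of wildtype; ``pKi`` is the binding affinity
    used for competition curves.
    """

    receptor: str = "wildtype"
    ligand: str = "GLP-1"
    pathway: str = "cAMP"
    log_tau: float = 1.22
    log_KA: float = -8.35
    E_m: float = 100.0
    slope_n: float = 1.0
    basal: float = 0.0
    expression_pct: float = 100.0
    pKi: float = np.nan

    def __post_init__(self):
        if not (self.E_m > self.basal >= 0):
            raise ValueError("require E_m > basal >= 0")
        if not self.slope_n > 0:
            raise ValueError("slope_n must be > 0")
        if not self.expression_pct > 0:
            raise ValueError("expression_pct must be > 0")


@dataclass(frozen=True)
class AssayDesign:
    """Concentration grid and replicate structure of one assay."""

    concentrations: np.ndarray
    n_experiments: int = DEFAULT_N_EXPERIMENTS
    n_technical_replicates: int = DEFAULT_N_DUPLICATES
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size == 0:
            raise ValueError("empty concentration grid")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be > 0")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "concentrations", conc)


@dataclass(frozen=True)
class ExpressionMeasurement:
    """Cell-surface expression summary, % of wildtype."""

    elisa_pct: float
    elisa_sem: float
    n: int
    bmax_pct: float | None = None
    bmax_sem: float | None = None

    def __post_init__(self):
        if not self.elisa_pct > 0:
            raise ValueError("expression must be > 0")


def default_concentrations(p_center: float, n: int = 9,
                           step_log: float = 0.5) -> np.ndarray:
    """Half-log-spaced molar grid of ``n`` concentrations centred on
    ``10**-p_center`` (e.g. the expected pEC50)."""
    logs = -p_center + step_log * (np.arange(n) - (n - 1) / 2)
    return 10.0 ** logs


def _stream(design: AssayDesign, *labels: str) -> np.random.Generator:
    """Independent per-curve RNG stream derived from the design seed and
    the curve's labels (stable across runs and label-insertion order)."""
    keys = [design.seed] + [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(keys))


def operational_response(conc, log_tau, log_KA, E_m=100.0, basal=0.0, n=1.0):
    """Operational-model (Black-Leff) response at molar concentration(s):

        E(A) = basal + (E_m - basal) * tau^n A^n / (tau^n A^n + (A + K_A)^n)
    """
    A = np.asarray(conc, dtype=float)
    tau = 10.0 ** log_tau
    KA = 10.0 ** log_KA
    num = (tau * A) ** n
    return basal + (E_m - basal) * num / (num + (A + KA) ** n)


def competition_response(conc_I, pKi, tracer_conc, tracer_pKd):
    """One-site competition: specific tracer binding (% of binding with no
    competitor) at competitor concentration(s) ``conc_I`` (molar):

        B([I]) = 100 / (1 + [I]/IC50),   IC50 = K_i (1 + [L]/K_d)
    """
    I = np.asarray(conc_I, dtype=float)
    Ki = 10.0 ** (-pKi)
    Kd = 10.0 ** (-tracer_pKd)
    ic50 = Ki * (1.0 + tracer_conc / Kd)
    return 100.0 / (1.0 + I / ic50)


def _noisy_curve(expected: np.ndarray, truth_labels, design: AssayDesign,
                 pathway: str) -> ResponseCurve:
    rng = _stream(design, *truth_labels, pathway)
    conc = design.concentrations
    n_exp = design.n_experiments
    concs, resps, exps = [], [], []
    for e in range(n_exp):
        noise = rng.normal(0.0, design.noise_sd, size=conc.size)
        concs.append(conc)
        resps.append(expected + noise)
        exps.append(np.full(conc.size, e, dtype=int))
    rec, lig = truth_labels
    return ResponseCurve(rec, lig, pathway,
                         np.concatenate(concs), np.concatenate(resps),
                         np.concatenate(exps))


def simulate_response_curve(truth: GroundTruth, design: AssayDesign) -> ResponseCurve:
    """Simulate per-experiment mean-of-duplicate responses for one curve.

    The expected value at each concentration is the operational-model
    response; Gaussian noise of SD ``design.noise_sd`` is added
    independently per experiment and concentration. A ``log_tau`` of NaN
    simulates a signal-free (ND) curve: basal plus noise.
    """
    if np.isnan(truth.log_tau):
        expected = np.full(design.concentrations.size, truth.basal)
    else:
        expected = operational_response(
            design.concentrations, truth.log_tau, truth.log_KA,
            truth.E_m, truth.basal, truth.slope_n)
    return _noisy_curve(expected, (truth.receptor, truth.ligand), design,
                        truth.pathway)


def simulate_competition_binding(pKi_unlabelled: float, tracer_conc: float,
                                 tracer_pKd: float, design: AssayDesign,
                                 receptor: str = "wildtype",
                                 ligand: str = "competitor") -> ResponseCurve:
    """Simulate a whole-cell competition-binding curve (pathway ``binding``).

    A NaN ``pKi_unlabelled`` simulates no detectable specific binding
    (flat noise around zero), the signature of a construct whose binding
    could not be experimentally defined.
    """
    if tracer_conc <= 0:
        raise ValueError("tracer_conc must be > 0")
    if np.isnan(pKi_unlabelled):
        expected = np.zeros(design.concentrations.size)
    else:
        expected = competition_response(design.concentrations, pKi_unlabelled,
                                        tracer_conc, tracer_pKd)
    return _noisy_curve(expected, (receptor, ligand), design, "binding")


def simulate_expression(truth_pct: float, cv: float, n: int,
                        seed: int) -> ExpressionMeasurement:
    """Simulate ELISA cell-surface expression as ``n`` lognormal draws whose
    mean equals ``truth_pct`` and whose coefficient of variation is ``cv``."""
    if truth_pct <= 0:
        raise ValueError("truth_pct must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    if cv == 0:
        draws = np.full(n, truth_pct)
    else:
        sigma = np.sqrt(np.log1p(cv ** 2))
        mu = np.log(truth_pct) - 0.5 * sigma ** 2
        draws = rng.lognormal(mu, sigma, size=n)
    sem = draws.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
    return ExpressionMeasurement(float(draws.mean()), float(sem), n)


def simulate_panel(truth: pd.DataFrame | None = None, *,
                   seed: int = 0,
                   n_experiments: int = DEFAULT_N_EXPERIMENTS,
                   noise_sd: float = DEFAULT_NOISE_SD,
                   expression_cv: float = 0.1,
                   n_conc: int = 9) -> dict[str, pd.DataFrame]:
    """Simulate a full mutant-panel study.

    ``truth`` is a ground-truth table with the columns of
    :func:`gpcrbias.reference.ground_truth_panel` (the default). Returns a
    dict of tidy DataFrames:

    * ``functional`` — long curve table (receptor, ligand, pathway,
      experiment, conc_M, response) for the signalling assays,
    * ``binding`` — same format with pathway ``binding`` (one curve per
      receptor x ligand, including the antagonist),
    * ``expression`` — receptor, elisa_pct, elisa_sem, n,
    * ``truth`` — the ground-truth table used (for recovery tests).

    Concentration grids are half-log spaced, centred per curve on the
    expected midpoint so every curve is well sampled.
    """
    if truth is None:
        truth = reference.ground_truth_panel()

    functional = []
    for row in truth.itertuples(index=False):
        if np.isnan(row.log_tau):
            center = 8.0  # arbitrary grid for a signal-free curve
        else:
            tau = 10.0 ** row.log_tau
            ec50 = 10.0 ** row.log_KA / (1.0 + tau)
            center = -np.log10(ec50)
        design = AssayDesign(default_concentrations(center, n=n_conc),
                             n_experiments=n_experiments, noise_sd=noise_sd,
                             seed=seed)
        gt = GroundTruth(row.receptor, row.ligand, row.pathway,
                         log_tau=row.log_tau if not np.isnan(row.log_tau) else np.nan,
                         log_KA=row.log_KA if not np.isnan(row.log_KA) else -8.0,
                         E_m=row.E_m, slope_n=row.slope_n, basal=row.basal,
                         expression_pct=row.expression_pct)
        functional.append(simulate_response_curve(gt, design).to_frame())

    # binding: one competition curve per receptor x ligand (incl. antagonist),
    # tracer K_d = that construct's antagonist pKi (the tracer is the
    # labelled antagonist); undefined binding simulates as flat noise.
    binding = []
    wt_ant = reference.AFFINITY[reference.WILDTYPE][reference.ANTAGONIST][0]
    for rec in truth["receptor"].unique():
        aff = reference.AFFINITY.get(rec, {})
        ant = aff.get(reference.ANTAGONIST)
        tracer_pKd = ant[0] if ant is not None else wt_ant
        for lig in reference.LIGANDS:
            entry = aff.get(lig)
            pki = entry[0] if entry is not None else np.nan
            center = pki if np.isfinite(pki) else 8.0
            design = AssayDesign(default_concentrations(center, n=n_conc),
                                 n_experiments=n_experiments,
                                 noise_sd=noise_sd, seed=seed)
            binding.append(simulate_competition_binding(
                pki, reference.TRACER_CONC_M, tracer_pKd, design,
                receptor=rec, ligand=lig).to_frame())

    expr_rows = []
    for i, rec in enumerate(truth["receptor"].unique()):
        pct = truth.loc[truth["receptor"] == rec, "expression_pct"].iloc[0]
        meas = simulate_expression(pct, expression_cv, n_experiments,
                                   seed=np.random.SeedSequence(
                                       [seed, zlib.crc32(rec.encode()), 7]).generate_state(1)[0] % (2**31))
        expr_rows.append({"receptor": rec, "elisa_pct": meas.elisa_pct,
                          "elisa_sem": meas.elisa_sem, "n": meas.n})

    return {
        "functional": pd.concat(functional, ignore_index=True),
        "binding": pd.concat(binding, ignore_index=True),
        "expression": pd.DataFrame(expr_rows),
        "truth": truth.reset_index(drop=True),
    }
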