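"""Competition radioligand-binding analysis.

A descending three-parameter logistic fit of specific-binding vs
unlabelled-competitor concentration yields pIC50; the Cheng-Prusoff
relation converts it to the competitor's equilibrium affinity,

    K_i = IC50 / (1 + [L]/K_d)   i.e.   pKi = pIC50 + log10(1 + [L]/K_d),

where [L] is the radiotracer concentration and K_d its affinity at the
construct under study. At tracer occupancies typical of these assays
([L] ~ 0.05 nM against sub-10-nM K_d) the correction is a shift of well
under 0.01 log units, but it is applied exactly. Affinity losses are
reported as fold changes, 10**(pKi_ref - pKi_mut).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dose_response import ResponseCurve, fit_logistic3, ND_SPAN_FACTOR

__all__ = ["BindingFit", "fit_competition", "ic50_to_ki", "fold_change",
           "round_fold"]


@dataclass
class BindingFit:
    """Competition-binding descriptors; ``nd`` marks no detectable
    displacement (e.g. a construct with no measurable specific binding)."""

    pIC50: float = np.nan
    pIC50_se: float = np.nan
    pKi: float = np.nan
    pKi_se: float = np.nan
    top: float = np.nan
    bottom: float = np.nan
    tracer_conc: float = np.nan
    tracer_pKd: float = np.nan
    converged: bool = False
    nd: bool = False


def fit_competition(curve: ResponseCurve, noise_sd_est: float | None = None,
                    nd_span_factor: float = ND_SPAN_FACTOR) -> BindingFit:
    """Fit a descending three-parameter logistic to a competition curve.

    Responses are % specific binding; top and bottom are estimated freely.
    Returns pIC50 with SE; a span below the ND threshold (no displacement)
    sets ``nd`` and leaves pIC50 undefined.
    """
    lf = fit_logistic3(curve, noise_sd_est=noise_sd_est,
                       nd_span_factor=nd_span_factor)
    fit = BindingFit(converged=lf.converged, nd=lf.nd)
    if lf.converged and not lf.nd:
        # descending convention: top = high-binding asymptote
        fit.pIC50, fit.pIC50_se = lf.pEC50, lf.pEC50_se
        fit.top = max(lf.Emax, lf.basal)
        fit.bottom = min(lf.Emax, lf.basal)
    return fit


def ic50_to_ki(pIC50: float, tracer_conc: float, tracer_pKd: float,
               pIC50_se: float = np.nan) -> tuple[float, float]:
    """Cheng-Prusoff occupancy correction on the -log10 scale.

    Returns ``(pKi, pKi_se)``; the correction is a deterministic shift, so
    the SE is carried through unchanged.
    """
    if tracer_conc < 0:
        raise ValueError("tracer_conc must be >= 0")
    if not math.isfinite(tracer_pKd):
        raise ValueError("tracer_pKd must be finite")
    Kd = 10.0 ** (-tracer_pKd)
    shift = math.log10(1.0 + tracer_conc / Kd)
    return pIC50 + shift, pIC50_se


def fold_change(p_ref: float, p_mut: float) -> float:
    """Fold change between two -log10 affinity/potency values.

    ``10**(p_ref - p_mut)``: > 1 means the mutant is weaker than the
    reference. Either input NaN (ND) propagates to NaN.
    """
    if p_ref is None or p_mut is None:
        return float("nan")
    return 10.0 ** (p_ref - p_mut)


def round_fold(fold: float) -> float:
    """Reporting helper: round a fold change half-away-from-zero to an
    integer, as fold losses are quoted in the text of panel studies."""
    if not math.isfinite(fold):
        return float("nan")
    return math.floor(abs(fold) + 0.5) * (1 if fold >= 0 else -1)
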