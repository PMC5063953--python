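"""Empirical concentration-response analysis.

Fits agonist concentration-response data with the three-parameter logistic
(Hill) equation

    E(A) = basal + (Emax - basal) / (1 + 10**(-pEC50 - log10 A))

with the Hill slope fixed at 1, returning pEC50 (-log10 molar EC50), Emax
and basal with asymptotic standard errors, and flags curves whose fitted
span is indistinguishable from noise as ND ("not determined").

Each y value entering the fit is the mean of technical replicates for one
independent experiment; the data are unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ResponseCurve", "LogisticFit", "fit_logistic3", "flag_nd",
    "logistic3", "CURVE_COLUMNS",
]

#: Canonical long-format curve CSV schema.
CURVE_COLUMNS = ["receptor", "ligand", "pathway", "experiment", "conc_M", "response"]

#: Default ND rule: fitted span must exceed ``ND_SPAN_FACTOR`` times the
#: noise SD estimate, and the midpoint must lie within the tested
#: concentration range extended by ``ND_RANGE_MARGIN`` log units.
ND_SPAN_FACTOR = 3.0
ND_RANGE_MARGIN = 1.0

#: Minimum number of distinct concentrations required for a 3-parameter fit.
MIN_DISTINCT_CONC = 4


@dataclass(frozen=True)
class ResponseCurve:
    """One receptor x ligand x pathway set of replicate measurements.

    ``conc`` is molar and strictly positive; ``response`` is on the
    normalized percentage scale (% of a system-maximal control for
    functional data, % specific binding for competition data);
    ``experiment`` labels the independent experiment each point came from.
    """

    receptor: str
    ligand: str
    pathway: str
    conc: np.ndarray
    response: np.ndarray
    experiment: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        conc = np.asarray(self.conc, dtype=float)
        resp = np.asarray(self.response, dtype=float)
        if conc.shape != resp.shape or conc.ndim != 1:
            raise ValueError("conc and response must be 1-D arrays of equal length")
        if conc.size == 0:
            raise ValueError("empty concentration grid")
        if np.any(conc <= 0):
            raise ValueError("all concentrations must be > 0 (molar)")
        exp = self.experiment
        if exp is None:
            exp = np.zeros(conc.size, dtype=int)
        else:
            exp = np.asarray(exp)
            if exp.shape != conc.shape:
                raise ValueError("experiment labels must match data length")
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "response", resp)
        object.__setattr__(self, "experiment", exp)

    @property
    def n_distinct_conc(self) -> int:
        return np.unique(self.conc).size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "receptor": self.receptor, "ligand": self.ligand,
            "pathway": self.pathway, "experiment": self.experiment,
            "conc_M": self.conc, "response": self.response,
        })

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "ResponseCurve":
        """Build a curve from one (receptor, ligand, pathway) slice of the
        canonical long-format table."""
        for col in CURVE_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"curve table missing column {col!r}")
        keys = df[["receptor", "ligand", "pathway"]].drop_duplicates()
        if len(keys) != 1:
            raise ValueError("from_frame expects a single receptor/ligand/pathway slice")
        rec, lig, pw = keys.iloc[0]
        return ResponseCurve(rec, lig, pw,
                             df["conc_M"].to_numpy(float),
                             df["response"].to_numpy(float),
                             df["experiment"].to_numpy())


@dataclass
class LogisticFit:
    """Three-parameter logistic curve descriptors with asymptotic SEs."""

    pEC50: float = np.nan
    pEC50_se: float = np.nan
    Emax: float = np.nan
    Emax_se: float = np.nan
    basal: float = np.nan
    basal_se: float = np.nan
    converged: bool = False
    nd: bool = False

    @property
    def span(self) -> float:
        return self.Emax - self.basal


def logistic3(conc, pEC50, Emax, basal):
    """Three-parameter logistic response at molar concentration(s)."""
    logA = np.log10(conc)
    return basal + (Emax - basal) / (1.0 + 10.0 ** (-pEC50 - logA))


def _descending_ok(y):
    # allow descending (competition-style) data: span sign is free
    return True


def fit_logistic3(curve: ResponseCurve, noise_sd_est: float | None = None,
                  nd_span_factor: float = ND_SPAN_FACTOR) -> LogisticFit:
    """Fit the three-parameter logistic equation to one curve.

    The Hill slope is fixed at 1; basal, Emax and the midpoint (on the
    log10 molar scale, reported as pEC50) are free. Standard errors come
    from the covariance of the unweighted least-squares fit. If
    ``noise_sd_est`` is given, the fitted curve is additionally screened by
    :func:`flag_nd`.

    Raises ``ValueError`` for degenerate inputs (fewer than four distinct
    concentrations, or all concentrations identical).
    """
    if curve.n_distinct_conc < MIN_DISTINCT_CONC:
        raise ValueError(
            f"need >= {MIN_DISTINCT_CONC} distinct concentrations, got "
            f"{curve.n_distinct_conc} for {curve.receptor}/{curve.ligand}/{curve.pathway}")
    y = curve.response
    conc = curve.conc
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")

    logc = np.log10(conc)
    lo, hi = float(y.min()), float(y.max())
    span0 = hi - lo
    # midpoint start: concentration whose mean response is nearest half-span
    order = np.argsort(logc)
    target = lo + 0.5 * span0
    mid0 = -logc[order][np.argmin(np.abs(y[order] - target))]
    # direction: ascending (agonism) vs descending (competition)
    slope_sign = np.polyfit(logc, y, 1)[0]
    if slope_sign >= 0:
        p0 = [mid0, hi, lo]
    else:
        p0 = [mid0, lo, hi]  # Emax < basal encodes a descending curve

    fit = LogisticFit()
    try:
        popt, pcov = curve_fit(
            logistic3, conc, y, p0=p0,
            bounds=([-np.log10(conc.max()) - 6, -np.inf, -np.inf],
                    [-np.log10(conc.min()) + 6, np.inf, np.inf]),
            maxfev=10000)
        se = np.sqrt(np.diag(pcov))
        fit = LogisticFit(pEC50=popt[0], pEC50_se=se[0],
                          Emax=popt[1], Emax_se=se[1],
                          basal=popt[2], basal_se=se[2],
                          converged=bool(np.all(np.isfinite(popt))))
    except (RuntimeError, ValueError):
        fit.converged = False

    fit.nd = flag_nd(fit, noise_sd_est, conc_range=(conc.min(), conc.max()),
                     k=nd_span_factor)
    return fit


def flag_nd(fit: LogisticFit, noise_sd_est: float | None = None,
            conc_range: tuple[float, float] | None = None,
            k: float = ND_SPAN_FACTOR) -> bool:
    """Decide whether a fitted curve is experimentally undefined (ND).

    A curve is ND when the fit did not converge, when its fitted span is
    below ``k`` times the noise SD estimate (default 3 sigma), or when the
    midpoint falls more than one log unit outside the tested concentration
    range (the asymptotes were never approached, so the parameters are not
    constrained by the data).
    """
    if not fit.converged:
        return True
    if noise_sd_est is not None and abs(fit.span) < k * noise_sd_est:
        return True
    if conc_range is not None and np.isfinite(fit.pEC50):
        cmin, cmax = conc_range
        lo_p = -np.log10(cmax) - ND_RANGE_MARGIN
        hi_p = -np.log10(cmin) + ND_RANGE_MARGIN
        if not (lo_p <= fit.pEC50 <= hi_p):
            return True
    return False
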