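"""Biased-agonism quantification.

A mutant's transduction coefficient for one ligand-pathway is first
normalized to the wildtype receptor,

    Dlog R = log(tau_c/K_A)_mut - log(tau_c/K_A)_wt ,

and the bias factor between two pathways is the difference of differences,

    DDlog R = Dlog R(pathway 1) - Dlog R(pathway 2),   linear = 10**DDlogR,

with uncertainties combined in quadrature at each step. A linear factor
above 1 denotes bias towards pathway 1. When one pathway has no detectable
signal (ND) the bias is not a number but its direction is known; exporters
materialize the plotting convention of +100 (bias towards pathway 1,
because pathway 2 is silent) or -100 (the reverse). Sentinels live in the
presentation layer only and never enter numeric aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operational import TransductionCoefficient
from .groupstats import anova_dunnett

__all__ = ["DeltaLogR", "BiasFactor", "delta_log_r", "bias_factor",
           "flag_significance", "SENTINEL_MAGNITUDE"]

SENTINEL_MAGNITUDE = 100.0


@dataclass
class DeltaLogR:
    """Wildtype-normalized change in a transduction coefficient."""

    receptor: str
    ligand: str
    pathway: str
    value: float = np.nan
    se: float = np.nan
    nd: bool = False


@dataclass
class BiasFactor:
    """Between-pathway bias of one mutant x ligand relative to wildtype.

    ``sentinel`` is ``0`` for a numeric result, ``+1``/``-1`` when pathway 2
    (resp. pathway 1) had no detectable signal so only the direction of
    bias is defined; exporters print it as +/-100.
    """

    receptor: str
    ligand: str
    pathway1: str
    pathway2: str
    ddlog_r: float = np.nan
    se: float = np.nan
    sentinel: int = 0
    significant: bool | None = None

    @property
    def linear(self) -> float:
        return 10.0 ** self.ddlog_r

    @property
    def nd(self) -> bool:
        return not np.isfinite(self.ddlog_r)

    def presentation_value(self) -> float:
        """Numeric value for radial-plot export: DDlogR, a +/-100 sentinel,
        or NaN when both pathways are undefined."""
        if self.sentinel:
            return SENTINEL_MAGNITUDE * self.sentinel
        return self.ddlog_r


def delta_log_r(mut: TransductionCoefficient,
                wt: TransductionCoefficient) -> DeltaLogR:
    """Normalize a mutant transduction coefficient to the wildtype.

    Requires matching ligand and pathway labels. SEs combine in
    quadrature; by convention the wildtype against itself is exactly 0
    with SE sqrt(2)*SE_wt, so the control's uncertainty is carried into
    downstream comparisons rather than silently dropped. ND in either
    input propagates.
    """
    if (mut.ligand, mut.pathway) != (wt.ligand, wt.pathway):
        raise ValueError(
            f"label mismatch: {(mut.ligand, mut.pathway)} vs "
            f"{(wt.ligand, wt.pathway)}")
    d = DeltaLogR(mut.receptor, mut.ligand, mut.pathway)
    if mut.nd or wt.nd:
        d.nd = True
        return d
    d.value = mut.log_r - wt.log_r
    d.se = float(np.hypot(mut.log_r_se, wt.log_r_se))
    return d


def bias_factor(d1: DeltaLogR, d2: DeltaLogR) -> BiasFactor:
    """Bias factor between two pathways for one mutant x ligand.

    ``d1`` and ``d2`` must share receptor and ligand and differ in
    pathway. ND handling: pathway 1 silent -> sentinel -1 (bias away from
    pathway 1); pathway 2 silent -> sentinel +1; both silent -> undefined,
    no sentinel.
    """
    if (d1.receptor, d1.ligand) != (d2.receptor, d2.ligand):
        raise ValueError("bias_factor requires matching receptor and ligand")
    if d1.pathway == d2.pathway:
        raise ValueError("bias_factor requires two different pathways")
    b = BiasFactor(d1.receptor, d1.ligand, d1.pathway, d2.pathway)
    if d1.nd and d2.nd:
        return b
    if d1.nd:
        b.sentinel = -1
        return b
    if d2.nd:
        b.sentinel = +1
        return b
    b.ddlog_r = d1.value - d2.value
    b.se = float(np.hypot(d1.se, d2.se))
    return b


def flag_significance(per_experiment: dict[str, np.ndarray],
                      control_id: str, alpha: float = 0.05,
                      rng=0) -> dict[str, bool]:
    """Dunnett many-to-one significance of bias estimates against control.

    ``per_experiment`` maps each receptor to its per-experiment DDlogR
    estimates (the control receptor's estimates scatter around 0 by
    construction). Returns a flag per non-control receptor: True when the
    Dunnett-adjusted p-value is below ``alpha``.
    """
    comp = anova_dunnett(per_experiment, control_id, alpha=alpha, rng=rng)
    return dict(zip(comp.group_ids, comp.significant))
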