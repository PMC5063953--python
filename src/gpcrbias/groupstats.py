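"""Many-to-one group comparisons: one-way ANOVA with Dunnett's post test.

Every mutant-vs-wildtype comparison in the pipeline (affinity, potency,
efficacy, expression, bias) runs through the same procedure: a one-way
analysis of variance across all groups, followed by Dunnett's two-sided
many-to-one test of each mutant against the single wildtype control, with
family-wise error control via the equicorrelated multivariate-t
distribution (scipy's implementation). Significance is accepted at
p < 0.05 by default.

When only summary statistics (mean, SEM, n) are available, replicate sets
are reconstituted by moment matching — a deterministic standardized score
vector scaled to the stated moments — which reproduces exactly the t
statistics the raw data would have given (clearly approximate for any
higher-moment behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison", "anova_dunnett", "summaries_from_replicates",
    "replicates_from_summary", "dunnett_critical_value", "simulate_null_fwer",
]


@dataclass
class GroupComparison:
    """Result of a one-way ANOVA + Dunnett many-to-one comparison."""

    parameter: str
    control_id: str
    control_mean: float
    control_sem: float
    control_n: int
    group_ids: list[str]
    means: np.ndarray
    sems: np.ndarray
    ns: np.ndarray
    f_statistic: float
    anova_p: float
    adjusted_p: np.ndarray
    alpha: float
    significant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.significant is None:
            self.significant = self.adjusted_p < self.alpha


def summaries_from_replicates(values) -> tuple[float, float, int]:
    """Arithmetic mean, SEM (= SD/sqrt(n), ddof=1) and n."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least two replicates")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(n)), n


def replicates_from_summary(mean: float, sem: float, n: int) -> np.ndarray:
    """Moment-matched surrogate replicates for summary-only data.

    A fixed symmetric score vector is standardized (ddof=1) and scaled so
    the surrogate set has exactly the stated mean and SEM. Approximate:
    only the first two moments are honoured.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    z = np.arange(n, dtype=float) - (n - 1) / 2
    z /= z.std(ddof=1)
    return mean + sem * np.sqrt(n) * z


def anova_dunnett(groups: dict[str, np.ndarray], control_id: str,
                  alpha: float = 0.05, parameter: str = "",
                  rng=0) -> GroupComparison:
    """One-way ANOVA F test plus Dunnett-adjusted mutant-vs-control p-values.

    ``groups`` maps group labels to replicate arrays; ``control_id`` names
    the control group. Equal variances are assumed (classical ANOVA);
    unbalanced group sizes are supported. ``rng`` seeds the numerical
    evaluation of the multivariate-t so results are reproducible.

    Raises ``ValueError`` when the control is absent, any group has fewer
    than two replicates, or the pooled variance is zero (degenerate data).
    """
    if control_id not in groups:
        raise ValueError(f"control group {control_id!r} absent")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 replicates")

    control = arrays[control_id]
    others = {k: v for k, v in arrays.items() if k != control_id}
    all_vals = list(arrays.values())
    pooled_ss = sum(((v - v.mean()) ** 2).sum() for v in all_vals)
    if pooled_ss == 0:
        raise ValueError("zero pooled variance: degenerate data")

    f_stat, anova_p = stats.f_oneway(*all_vals)
    res = stats.dunnett(*others.values(), control=control,
                        alternative="two-sided",
                        rng=np.random.default_rng(rng))

    ids = list(others)
    means = np.array([others[k].mean() for k in ids])
    sems = np.array([others[k].std(ddof=1) / np.sqrt(others[k].size) for k in ids])
    ns = np.array([others[k].size for k in ids])
    c_mean, c_sem, c_n = summaries_from_replicates(control)
    return GroupComparison(parameter=parameter, control_id=control_id,
                           control_mean=c_mean, control_sem=c_sem,
                           control_n=c_n, group_ids=ids, means=means,
                           sems=sems, ns=ns, f_statistic=float(f_stat),
                           anova_p=float(anova_p),
                           adjusted_p=np.asarray(res.pvalue), alpha=alpha)


def dunnett_critical_value(k: int, n_per_group: int, n_control: int | None = None,
                           alpha: float = 0.05, rng=0) -> float:
    """Two-sided Dunnett critical value |t| for k comparisons (balanced or
    one control size), extracted from the simultaneous confidence interval
    of a probe dataset (the interval halfwidth is c * SE by construction,
    so the geometry of the probe data cancels)."""
    n_control = n_control or n_per_group
    gen = np.random.default_rng(12345)
    groups = [gen.normal(size=n_per_group) for _ in range(k)]
    control = gen.normal(size=n_control)
    res = stats.dunnett(*groups, control=control,
                        rng=np.random.default_rng(rng))
    ci = res.confidence_interval(1 - alpha)
    dfd = k * n_per_group + n_control - (k + 1)
    sp2 = sum(((g - g.mean()) ** 2).sum() for g in groups + [control]) / dfd
    se = np.sqrt(sp2 * (1 / n_per_group + 1 / n_control))
    half = (np.asarray(ci.high) - np.asarray(ci.low)) / 2
    return float(half[0] / se)


def simulate_null_fwer(k: int = 12, n: int = 5, alpha: float = 0.05,
                       n_sims: int = 10_000, seed: int = 0) -> float:
    """Empirical family-wise error rate of the Dunnett decision rule under
    a global null (all groups from one normal distribution).

    Vectorized over simulations: a family commits an error iff
    max_i |t_i| exceeds the Dunnett critical value, which is the same
    event as min_i adjusted-p < alpha.
    """
    crit = dunnett_critical_value(k, n, alpha=alpha)
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(n_sims, k + 1, n))  # group 0 is the control
    means = data.mean(axis=2)
    ss = ((data - means[..., None]) ** 2).sum(axis=(1, 2))
    dfd = (k + 1) * (n - 1)
    sp2 = ss / dfd
    se = np.sqrt(sp2 * (2.0 / n))
    t = (means[:, 1:] - means[:, [0]]) / se[:, None]
    return float((np.abs(t).max(axis=1) > crit).mean())
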