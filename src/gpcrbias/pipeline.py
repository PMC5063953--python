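"""Pipeline orchestration and publication-style reporting.

Composes the analysis stages in assay order — simulate (or load)
concentration-response, competition-binding and expression data; fit
empirical logistic curves; derive binding affinities with the
radioligand-occupancy correction; fit the operational model globally and
correct efficacies to surface expression; quantify pathway bias against
the wildtype; run Dunnett many-to-one statistics — and writes the CSV
analogues of publication-style mutant-panel tables plus a radial-plot
export and
a plain-text run log.

Given the same configuration and master seed the emitted CSVs are
byte-identical across reruns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .dose_response import ResponseCurve, fit_logistic3, CURVE_COLUMNS
from .binding import fit_competition, ic50_to_ki, fold_change
from .operational import (fit_operational, fit_transduction_ratio,
                          correct_to_expression, TransductionCoefficient)
from .synthetic import ExpressionMeasurement, simulate_panel
from .bias import delta_log_r, bias_factor, BiasFactor
from .groupstats import anova_dunnett, replicates_from_summary

__all__ = ["RunConfig", "run_pipeline", "render_linear", "parse_linear",
           "SchemaError", "FitError", "validate_curve_table"]

log = logging.getLogger("gpcrbias")


class SchemaError(ValueError):
    """Input table violates the canonical schema."""


class FitError(RuntimeError):
    """A fitting stage failed irrecoverably."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    With no input paths the synthetic full panel is generated from
    ``seed``. ``em`` anchors the operational-model system maximum on the
    normalized response scale (100 = the system-maximal control);
    ``em=None`` estimates it, subject to the identifiability caveat in
    :mod:`gpcrbias.operational`. ``nd_span_factor`` is the k of the
    k-sigma ND rule; ``slope_mode`` is ``"estimated"`` or ``"fixed1"``.
    """

    functional_csv: str | None = None
    binding_csv: str | None = None
    expression_csv: str | None = None
    output_dir: str = "gpcrbias_out"
    seed: int = 0
    nd_span_factor: float = 3.0
    slope_mode: str = "estimated"
    em: float | None = 100.0
    tracer_conc: float = reference.TRACER_CONC_M
    alpha: float = 0.05
    n_experiments: int = 5
    noise_sd: float = 5.0
    expression_cv: float = 0.1

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for p in (self.functional_csv, self.binding_csv, self.expression_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(payload) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**payload)


def validate_curve_table(df: pd.DataFrame, name: str = "curves") -> None:
    """Schema check for the canonical long curve CSV; errors cite rows."""
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")
    bad = df.index[~(pd.to_numeric(df["conc_M"], errors="coerce") > 0)]
    if len(bad):
        raise SchemaError(f"{name}: non-positive or non-numeric conc_M at "
                          f"rows {list(bad[:10])}")
    bad = df.index[pd.to_numeric(df["response"], errors="coerce").isna()]
    if len(bad):
        raise SchemaError(f"{name}: non-numeric response at rows {list(bad[:10])}")


def render_linear(value_log: float) -> str:
    """Antilog a log10 quantity and format it to two significant figures,
    rounding half away from zero — the convention of linear values printed
    in parentheses next to log-scale table entries (1.22 -> "17")."""
    value_log = float(value_log)
    if not math.isfinite(value_log):
        return "ND"
    x = 10.0 ** value_log
    d = Decimal(repr(x))
    exp = d.adjusted()
    q = d.scaleb(1 - exp).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    if q.adjusted() > 1:  # 99.5+ rounded up a digit
        exp += 1
        q = d.scaleb(1 - exp).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    val = q.scaleb(exp - 1)
    if exp >= 1:
        return str(int(val))
    return format(val, "f")


def parse_linear(text: str) -> float:
    """Inverse of :func:`render_linear` up to its printed precision."""
    return float(text)


def _estimate_noise_sd(curve: ResponseCurve) -> float:
    """Replicate scatter: mean per-concentration SD across experiments."""
    df = curve.to_frame()
    sds = df.groupby("conc_M")["response"].std(ddof=1).dropna()
    if len(sds) == 0:
        return 0.0
    return float(sds.mean())


def _curves_from_table(df: pd.DataFrame) -> list[ResponseCurve]:
    out = []
    for _, sub in df.groupby(["receptor", "ligand", "pathway"], sort=False):
        out.append(ResponseCurve.from_frame(sub))
    return out


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full analysis; returns the result tables and writes
    them (plus ``run.log``) under ``config.output_dir``.

    Tables: ``logistic_fits``, ``binding``, ``transduction``, ``bias``,
    ``stats``, ``radial``. Failures of a single receptor x ligand x
    pathway are logged and isolated; they surface as ND rows.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _load_inputs(config: RunConfig):
    if config.functional_csv is None:
        log.info("no input paths: simulating synthetic panel, seed=%d", config.seed)
        data = simulate_panel(seed=config.seed,
                              n_experiments=config.n_experiments,
                              noise_sd=config.noise_sd,
                              expression_cv=config.expression_cv)
        return data["functional"], data["binding"], data["expression"]
    functional = pd.read_csv(config.functional_csv)
    binding = (pd.read_csv(config.binding_csv)
               if config.binding_csv else pd.DataFrame(columns=CURVE_COLUMNS))
    if config.expression_csv:
        expression = pd.read_csv(config.expression_csv)
    else:
        raise SchemaError("expression_csv is required when loading data")
    return functional, binding, expression


def _expression_map(expression: pd.DataFrame) -> dict[str, ExpressionMeasurement]:
    need = {"receptor", "elisa_pct", "elisa_sem"}
    if not need <= set(expression.columns):
        raise SchemaError(f"expression table needs columns {sorted(need)}")
    out = {}
    for row in expression.itertuples(index=False):
        out[row.receptor] = ExpressionMeasurement(
            elisa_pct=float(row.elisa_pct), elisa_sem=float(row.elisa_sem),
            n=int(getattr(row, "n", 0) or 0) or 1)
    return out


def _run(config: RunConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    functional, binding_tbl, expression = _load_inputs(config)
    validate_curve_table(functional, "functional")
    if len(binding_tbl):
        validate_curve_table(binding_tbl, "binding")
    expr_map = _expression_map(expression)
    wt = reference.WILDTYPE

    # ---- stage 1: empirical logistic fits --------------------------------
    logistic_rows = []
    curves = _curves_from_table(functional)
    curve_fits = {}
    for c in curves:
        noise = _estimate_noise_sd(c)
        try:
            f = fit_logistic3(c, noise_sd_est=noise,
                              nd_span_factor=config.nd_span_factor)
        except ValueError as exc:
            log.warning("logistic fit skipped for %s/%s/%s: %s",
                        c.receptor, c.ligand, c.pathway, exc)
            continue
        curve_fits[(c.receptor, c.ligand, c.pathway)] = (c, f, noise)
        if f.nd:
            log.info("ND: %s/%s/%s (span %.2f, noise %.2f)",
                     c.receptor, c.ligand, c.pathway, f.span, noise)
        logistic_rows.append({
            "receptor": c.receptor, "ligand": c.ligand, "pathway": c.pathway,
            "pEC50": f.pEC50, "pEC50_se": f.pEC50_se, "Emax": f.Emax,
            "Emax_se": f.Emax_se, "basal": f.basal, "basal_se": f.basal_se,
            "converged": f.converged, "nd": f.nd})
    logistic_df = pd.DataFrame(logistic_rows)

    # ---- stage 2: competition binding -> pKi -----------------------------
    binding_df = _binding_stage(binding_tbl, expr_map, config)

    # ---- stage 3: operational fits + expression correction ---------------
    transduction_df, coefficients = _operational_stage(
        functional, curve_fits, expr_map, config)

    # ---- stage 4: bias quantification ------------------------------------
    bias_df, radial_df = _bias_stage(coefficients, config)

    # ---- stage 5: group statistics ---------------------------------------
    stats_df = _stats_stage(logistic_df, binding_df, transduction_df, config)

    results = {"logistic_fits": logistic_df, "binding": binding_df,
               "transduction": transduction_df, "bias": bias_df,
               "radial": radial_df, "stats": stats_df}
    for name, df in results.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
        log.info("wrote %s.csv (%d rows)", name, len(df))
    return results


def _binding_stage(binding_tbl, expr_map, config) -> pd.DataFrame:
    if not len(binding_tbl):
        return pd.DataFrame(columns=["receptor", "ligand", "pIC50", "pIC50_se",
                                     "pKi", "pKi_se", "nd"])
    fits = {}
    for _, sub in binding_tbl.groupby(["receptor", "ligand"], sort=False):
        c = ResponseCurve.from_frame(sub)
        noise = _estimate_noise_sd(c)
        try:
            fits[(c.receptor, c.ligand)] = fit_competition(
                c, noise_sd_est=noise, nd_span_factor=config.nd_span_factor)
        except ValueError as exc:
            log.warning("binding fit failed for %s/%s: %s",
                        c.receptor, c.ligand, exc)

    # tracer affinity per construct: the fitted affinity of the unlabelled
    # form of the tracer at that construct, corrected against itself
    # (the shift is < 0.01 log units at 0.05 nM tracer, so one pass is
    # exact to reporting precision); fall back to wildtype when undefined.
    ant = reference.TRACER_LIGAND
    wt_fit = fits.get((reference.WILDTYPE, ant))
    rows = []
    receptors = binding_tbl["receptor"].unique()
    for rec in receptors:
        own = fits.get((rec, ant))
        if own is not None and not own.nd:
            tracer_pkd = own.pIC50  # uncorrected; see note above
        elif wt_fit is not None and not wt_fit.nd:
            tracer_pkd = wt_fit.pIC50
            log.warning("tracer affinity undefined at %s; using wildtype", rec)
        else:
            tracer_pkd = np.nan
        for lig in binding_tbl.loc[binding_tbl["receptor"] == rec, "ligand"].unique():
            f = fits.get((rec, lig))
            if f is None or f.nd or not np.isfinite(tracer_pkd):
                rows.append({"receptor": rec, "ligand": lig, "pIC50": np.nan,
                             "pIC50_se": np.nan, "pKi": np.nan,
                             "pKi_se": np.nan, "nd": True})
                continue
            pki, pki_se = ic50_to_ki(f.pIC50, config.tracer_conc, tracer_pkd,
                                     f.pIC50_se)
            f.pKi, f.pKi_se = pki, pki_se
            f.tracer_conc, f.tracer_pKd = config.tracer_conc, tracer_pkd
            rows.append({"receptor": rec, "ligand": lig, "pIC50": f.pIC50,
                         "pIC50_se": f.pIC50_se, "pKi": pki, "pKi_se": pki_se,
                         "nd": False})
    df = pd.DataFrame(rows)
    wt_rows = df[df["receptor"] == reference.WILDTYPE].set_index("ligand")
    df["fold_vs_wildtype"] = [
        fold_change(wt_rows.loc[r.ligand, "pKi"], r.pKi)
        if r.ligand in wt_rows.index else np.nan
        for r in df.itertuples(index=False)]
    return df


def _operational_stage(functional, curve_fits, expr_map, config):
    coefficients: dict[tuple[str, str, str], TransductionCoefficient] = {}
    rows = []
    for (rec, pw), sub in functional.groupby(["receptor", "pathway"], sort=False):
        group = [c for (r, l, p), (c, f, n) in curve_fits.items()
                 if r == rec and p == pw]
        noise = np.mean([curve_fits[(rec, c.ligand, pw)][2] for c in group]) \
            if group else None
        expr = expr_map.get(rec)
        try:
            op = fit_operational(group, em=config.em,
                                 slope_mode=config.slope_mode,
                                 noise_sd_est=noise)
            ratio = fit_transduction_ratio(group, em=config.em,
                                           slope_mode=config.slope_mode,
                                           noise_sd_est=noise)
        except (ValueError, FitError) as exc:
            log.warning("operational fit failed for %s/%s: %s", rec, pw, exc)
            op, ratio = {}, {}
        for c in group:
            lig = c.ligand
            o = op.get(lig)
            r = ratio.get(lig)
            tc = TransductionCoefficient(rec, lig, pw, nd=True)
            if o is not None and r is not None and not o.nd and not r.nd \
                    and expr is not None:
                ltc, ltc_se = correct_to_expression(o.log_tau, o.log_tau_se, expr)
                lr, lr_se = correct_to_expression(r.log_ratio, r.log_ratio_se, expr)
                tc = TransductionCoefficient(rec, lig, pw, log_r=lr,
                                             log_r_se=lr_se, log_tau_c=ltc,
                                             log_tau_c_se=ltc_se, nd=False)
                if o.wide_se:
                    log.info("wide K_A SE for %s/%s/%s (%.2f)", rec, lig, pw,
                             o.log_KA_se)
            coefficients[(rec, lig, pw)] = tc
            rows.append({
                "receptor": rec, "ligand": lig, "pathway": pw,
                "log_tau": np.nan if o is None or o.nd else o.log_tau,
                "log_tau_se": np.nan if o is None or o.nd else o.log_tau_se,
                "neg_log_KA": np.nan if o is None or o.nd else -o.log_KA,
                "neg_log_KA_se": np.nan if o is None or o.nd else o.log_KA_se,
                "log_tau_c": tc.log_tau_c, "log_tau_c_se": tc.log_tau_c_se,
                "log_tau_c_linear": render_linear(tc.log_tau_c),
                "log_r": tc.log_r, "log_r_se": tc.log_r_se,
                "nd": tc.nd})
    return pd.DataFrame(rows), coefficients


def _bias_stage(coefficients, config):
    wt = reference.WILDTYPE
    bias_rows, radial_rows = [], []
    keys = sorted({(lig, pw) for (_, lig, pw) in coefficients})
    receptors = sorted({r for (r, _, _) in coefficients})

    deltas = {}
    for (lig, pw) in keys:
        wt_tc = coefficients.get((wt, lig, pw))
        if wt_tc is None:
            continue
        for rec in receptors:
            tc = coefficients.get((rec, lig, pw))
            if tc is None:
                continue
            if rec == wt:
                d = delta_log_r(wt_tc, wt_tc)
                if not d.nd:
                    d.value = 0.0  # exact by construction; SE carries sqrt(2)*SE_wt
            else:
                d = delta_log_r(tc, wt_tc)
            deltas[(rec, lig, pw)] = d

    pairs = reference.PATHWAY_PAIRS
    factors: dict[tuple[str, str, tuple[str, str]], BiasFactor] = {}
    for rec in receptors:
        for lig in sorted({l for (_, l, _) in coefficients}):
            for (p1, p2) in pairs:
                d1, d2 = deltas.get((rec, lig, p1)), deltas.get((rec, lig, p2))
                if d1 is None or d2 is None:
                    continue
                b = bias_factor(d1, d2)
                factors[(rec, lig, (p1, p2))] = b

    # significance per (ligand, pair): Dunnett across mutants with
    # moment-matched per-experiment surrogates; wildtype is the control.
    n_rep = config.n_experiments
    for lig in sorted({l for (_, l, _) in coefficients}):
        for (p1, p2) in pairs:
            groups = {}
            wt_b = factors.get((wt, lig, (p1, p2)))
            if wt_b is None or wt_b.nd:
                continue
            groups[wt] = replicates_from_summary(0.0, wt_b.se, n_rep)
            for rec in receptors:
                if rec == wt:
                    continue
                b = factors.get((rec, lig, (p1, p2)))
                if b is not None and not b.nd:
                    groups[rec] = replicates_from_summary(b.ddlog_r, b.se, n_rep)
            if len(groups) < 2:
                continue
            comp = anova_dunnett(groups, wt, alpha=config.alpha,
                                 parameter=f"bias:{lig}:{p1}-{p2}",
                                 rng=config.seed)
            flags = dict(zip(comp.group_ids, comp.significant))
            for rec, sig in flags.items():
                factors[(rec, lig, (p1, p2))].significant = bool(sig)

    for (rec, lig, (p1, p2)), b in sorted(factors.items()):
        bias_rows.append({
            "receptor": rec, "ligand": lig, "pathway1": p1, "pathway2": p2,
            "ddlog_r": b.ddlog_r, "se": b.se,
            "linear": render_linear(b.ddlog_r),
            "sentinel": b.sentinel * 100 if b.sentinel else 0,
            "significant": b.significant})
        radial_rows.append({
            "mutant": rec, "ligand": lig, "pair": f"{p1}-{p2}",
            "value_or_sentinel": b.presentation_value(),
            "significant": b.significant})
    return pd.DataFrame(bias_rows), pd.DataFrame(radial_rows)


def _stats_stage(logistic_df, binding_df, transduction_df, config):
    """Mutant-vs-wildtype Dunnett comparisons for each fitted parameter."""
    wt = reference.WILDTYPE
    n_rep = config.n_experiments
    rows = []

    def compare(df, value_col, se_col, label_cols, param):
        if not len(df):
            return
        for key, sub in df.groupby(label_cols, sort=False):
            sub = sub.dropna(subset=[value_col, se_col])
            sub = sub[sub[se_col] > 0] if len(sub) else sub
            if wt not in set(sub["receptor"]):
                continue
            groups = {}
            for r in sub.itertuples(index=False):
                groups[r.receptor] = replicates_from_summary(
                    getattr(r, value_col), getattr(r, se_col), n_rep)
            if len(groups) < 2:
                continue
            name = param + ":" + ":".join(np.atleast_1d(key).astype(str))
            try:
                comp = anova_dunnett(groups, wt, alpha=config.alpha,
                                     parameter=name, rng=config.seed)
            except ValueError as exc:
                log.warning("stats skipped for %s: %s", name, exc)
                continue
            for gid, mean, se, n, p, sig in zip(
                    comp.group_ids, comp.means, comp.sems, comp.ns,
                    comp.adjusted_p, comp.significant):
                rows.append({"parameter": name, "receptor": gid,
                             "estimate": mean, "se": se, "n": n,
                             "adj_p": p, "significant": bool(sig)})

    compare(binding_df, "pKi", "pKi_se", ["ligand"], "pKi")
    if len(logistic_df):
        ok = logistic_df[~logistic_df["nd"]]
        compare(ok, "pEC50", "pEC50_se", ["ligand", "pathway"], "pEC50")
    if len(transduction_df):
        ok = transduction_df[~transduction_df["nd"]]
        compare(ok, "log_tau_c", "log_tau_c_se", ["ligand", "pathway"],
                "log_tau_c")
    return pd.DataFrame(rows)
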