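# Methods

## Scope and data model

The package analyses endpoint, normalized pharmacology data from receptor
mutant panels: agonist concentration–response curves (response as % of a
system-maximal control, e.g. 100 μM forskolin for cAMP), whole-cell
competition binding (% specific tracer binding), and cell-surface
expression (% of wildtype, ELISA). The canonical exchange format is a
long CSV with columns `receptor, ligand, pathway, experiment, conc_M,
response`; each response value is the mean of technical duplicates for
one independent experiment and enters every fit as a single unweighted
point.

## Empirical curve fitting

`fit_logistic3` fits E = basal + (E_max − basal)/(1 + 10^(−pEC50 − log10 A))
— the three-parameter logistic with Hill slope fixed at 1 — by bounded
least squares with the midpoint parameterized on the log₁₀ molar scale,
where sampling errors are approximately normal and mean ± SEM reporting
is meaningful. Starting values are deterministic (basal = min response,
E_max = max response, midpoint = concentration nearest half-span, with
the sign of a linear-trend prefit choosing ascending vs descending
orientation), so refits are exactly reproducible. A four-parameter
variant (free slope) exists on the logistic model function but headline
outputs always use the fixed-slope form. Basal is estimated freely
rather than pinned to 0, since normalized data can sit slightly off zero.

**ND rule.** A curve is "not determined" when the fit fails to converge,
when the fitted span is below k·σ̂ (k = 3 by default; σ̂ is the mean
per-concentration replicate SD), or when the fitted midpoint lies more
than one log unit outside the tested concentration range. The 3σ choice
is conventional; with the default noise level (5% response units) it
reproduces the qualitative ND pattern of weak responders in the reference
panel (plateaus below ~15% of system max are undetectable — by design,
since the generator emulates assays in which such responses genuinely
drown in noise). Curves with fewer than four distinct concentrations, or
with all concentrations identical, are a hard error, not ND.

## Competition binding

One-site competition curves are fit with the same descending logistic,
yielding pIC₅₀. Cheng–Prusoff converts to affinity: pK_i = pIC₅₀ +
log₁₀(1 + [L]/K_d). The tracer K_d at each construct is that construct's
own fitted affinity for the unlabelled form of the tracer; when that is
undefined the wildtype value substitutes, with a logged warning — at the
default tracer concentration (0.05 nM) the whole correction is < 0.01
log units, so the fallback cannot distort conclusions. For the same
reason the construct's *uncorrected* pIC₅₀ of the tracer ligand stands in
for its K_d (iterating the correction to a fixed point would change the
answer by far less than the reporting precision). The correction is a
deterministic shift, so the pIC₅₀ SE carries through unchanged. Fold
affinity changes are 10^(pK_ref − pK_mut), reported rounded
half-away-from-zero to an integer.

## Operational model

The Black–Leff operational model is fit globally per receptor × pathway:
E_m, basal and the transducer slope n are shared across ligands, log τ
and log K_A are free per ligand. Sharing is what makes K_A of near-full
agonists estimable at all, and mirrors standard practice for transduction-
coefficient analysis. All magnitude parameters are estimated on the log₁₀
scale; n is bounded to [0.5, 3] with start 1. Standard errors and the
per-ligand (log τ, log K_A) covariance come from the Gauss–Newton
approximation at the optimum.

**System-maximum identifiability.** With n = 1 the operational curve for
*any* E_m ≥ the observed plateau reproduces a logistic exactly (apparent
maximum E_m τ/(1+τ), EC₅₀ = K_A/(1+τ)), so E_m is structurally
unidentifiable from agonist curves alone — a ridge, not a noise problem.
Two resolutions are supported: pass `em=` to anchor the system maximum
externally (the pipeline default anchors E_m = 100, exact on a response
scale normalized to a system-maximal control), or leave E_m free, in
which case a non-unit slope identifies it and the n = 1 degeneracy
surfaces as a wide-SE flag on log K_A (threshold: SE > 2 log units)
rather than a silent failure.

**Direct ratio fit.** The transduction coefficient is re-estimated from
the reparameterized model E = basal + (E_m−basal)(RA)ⁿ/((RA)ⁿ + (1+A/K_A)ⁿ)
with R = τ/K_A on the log₁₀ scale, so SE(log R) is read off the
covariance. On noiseless data it equals log τ − log K_A from the
two-parameter fit to numerical tolerance; on noisy data it equals the
covariance-aware composition. Note that with the slope *estimated*, log τ
and log K_A acquire a strong negative correlation through n and the true
SE(log R) legitimately *exceeds* the naive uncorrelated quadrature — the
familiar claim that the direct ratio is tighter than the naive
combination holds in the fixed-slope (n = 1) analysis.

**Expression correction.** log τ_c = log τ + log₁₀(100/expr%), with
SE² = SE(log τ)² + (SEM_expr/(expr·ln10))² by the delta method; the same
shift corrects log(τ/K_A) to log(τ_c/K_A). ELISA expression is the
source (a construct can lose radioligand binding yet still express).
Corrections compose exactly (50% then 200% returns the original). ND
expression makes τ_c ND.

## Bias quantification

Δlog R = log(τ_c/K_A)_mut − log(τ_c/K_A)_wt per ligand-pathway, and
ΔΔlog R between two pathways, each with quadrature SEs. The wildtype row
is 0 by construction but carries SE √2·SE_wt, so the control's
uncertainty is not silently dropped from downstream tests. ΔΔlog R is
antisymmetric under pathway swap and satisfies the triangle identity
exactly (it is a difference of shared terms). When exactly one pathway of
a pair is ND, the bias direction is known but not its magnitude: the data
model stores ND plus direction, and only exporters materialize the ±100
plotting sentinel; sentinel rows carry NaN in numeric columns so they can
never leak into aggregation.

## Statistics

Every mutant-vs-wildtype family (pK_i, pEC₅₀, log τ_c, expression, bias)
uses one-way ANOVA plus Dunnett's two-sided many-to-one test at α = 0.05,
assuming equal variances, with unbalanced n supported. The implementation
is scipy's equicorrelated multivariate-t Dunnett test, seeded for
reproducibility. Where only mean ± SEM summaries exist (e.g. bias factors
assembled from fit SEs), surrogate replicate sets are reconstituted by
moment matching — a fixed standardized score vector scaled to the stated
mean and SEM, n = 5 by default within the four-to-six range of the
emulated design — which reproduces exactly the t statistics the raw data
would give while honouring only the first two moments. The null
family-wise error rate is validated by simulation using the Dunnett
critical value (extracted from the simultaneous confidence interval,
2.87 at k = 12, df = 52): rejecting when max|t| exceeds it is the same
event as min adjusted-p < α, and vectorizes to 10⁴ simulated families in
well under a second.

## Synthetic data

The generator draws from the same forward models the fitting stages
assume: operational-model responses with additive, homoscedastic Gaussian
noise on the normalized scale (default SD 5 response units — chosen to
put fitted pEC₅₀ SEMs in the 0.06–0.2 log-unit range typical of such
panels), 5 independent experiments per curve by default, 9 half-log-
spaced concentrations centred per curve on the expected midpoint.
Expression noise is lognormal (CV 0.1) so simulated expression stays
positive; the lognormal is mean-parameterized so the expectation equals
the true level exactly. Each (receptor, ligand, pathway) curve has its
own RNG stream derived from the master seed and CRC32s of the labels, so
panels are reproducible and insertion-order independent. Ground-truth ND
entries simulate as flat noise (signal-free curves), exercising the ND
machinery downstream.

What the generator does **not** emulate: plate/batch effects, raw
luminescence scales, heteroscedastic or correlated noise, kinetic traces,
receptor reserve differences between assays beyond what τ encodes. Tests
passing on this synthetic world therefore validate the estimators and
error propagation under the stated noise model, not robustness to every
artefact of real plates.

The default ground truth is the reference GLP-1R panel
(`gpcrbias.reference`): 13 constructs × 3 agonists × 3 pathways with
E_m = 100, basal = 0, n = 1, raw log τ back-computed from the
expression-corrected reference efficacies.

## Problem sizes used in validation

Monte-Carlo checks use: 500 noisy logistic curves (bias/SE calibration),
150 three-ligand global ratio fits (accuracy and 95%-interval coverage),
10⁵ draws for error-propagation oracles, 10⁴ simulated families for the
Dunnett FWER, and the full 13 × 3 × 3 panel for the end-to-end pipeline
(≈ 7 s on one core). These sizes make sampling error small relative to
the tested tolerances while keeping the suite quick to run.

## Known limitations

* The operational τ of a near-full agonist is intrinsically ill-
  determined (plateau → τ is steep near the system maximum): its log τ
  scatters far more than log(τ/K_A), which is the quantity bias analysis
  rests on. This mirrors the model's geometry, not an implementation
  defect.
* Anchoring E_m = 100 is exact only when the normalization control truly
  spans the system maximum for that pathway; a mis-set anchor biases τ
  (but not log(τ/K_A), which is anchor-invariant along the n = 1 ridge).
* No depletion-corrected or two-site binding, no kinetic models, no
  constitutive-activity (inverse agonism) fitting.
* Moment-matched surrogate replicates assume approximately normal
  per-experiment estimates; heavy-tailed fit errors would make the
  Dunnett p-values approximate.
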