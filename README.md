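# gpcrbias

Quantitative pharmacology of GPCR mutant panels: concentration–response
and competition-binding curve fitting, operational-model efficacy
estimation, expression-corrected transduction coefficients, and
biased-agonism quantification with propagated uncertainty.

## The problem

Alanine-scanning a receptor like the glucagon-like peptide-1 receptor
(GLP-1R, class B GPCR) produces, for every mutant, concentration–response
curves for several agonists across several signalling pathways (cAMP
accumulation, ERK1/2 phosphorylation, intracellular Ca²⁺), whole-cell
competition-binding curves, and cell-surface expression measurements.
Deciding whether a mutation changes *affinity*, *efficacy* or *pathway
preference* — rather than merely expression — requires a mechanistic
model and careful error propagation. This package implements that
analysis chain as a reusable, tested pipeline for pharmacologists working
with such panels.

## The model

Empirical curves are described by the three-parameter logistic equation
(Hill slope 1), giving pEC₅₀ and E_max. Mechanistic efficacy uses the
Black–Leff operational model of agonism,

    E(A) = basal + (E_m − basal) · τⁿAⁿ / (τⁿAⁿ + (A + K_A)ⁿ),

fit globally per receptor × pathway (E_m, basal, n shared across ligands;
log τ, log K_A free per ligand). Efficacies are corrected to wildtype
surface expression, log τ_c = log τ + log₁₀(100/expr%), with delta-method
error propagation. A reparameterized fit estimates the transduction
coefficient log(τ/K_A) directly, so its standard error comes from the fit
covariance. Bias is quantified relative to wildtype:

    Δlog R  = log(τ_c/K_A)_mut − log(τ_c/K_A)_wt          (per pathway)
    ΔΔlog R = Δlog R(pathway 1) − Δlog R(pathway 2),      10^ΔΔlogR = bias factor

with quadrature SEs at each step. Binding IC₅₀ values are corrected for
radioligand occupancy by Cheng–Prusoff, pK_i = pIC₅₀ + log₁₀(1+[L]/K_d).
All mutant-vs-wildtype comparisons use one-way ANOVA with Dunnett's
two-sided many-to-one post test (p < 0.05). Pathways with no detectable
signal propagate as ND and appear in bias exports as ±100 sentinels
(direction of bias known, magnitude not).

Because no raw assay data are deposited for such panels, the package
ships a synthetic-data generator whose ground truth defaults to a
reference characterization of the GLP-1R wildtype plus twelve
transmembrane-boundary alanine mutants × three agonists × three pathways
(`gpcrbias.reference`), so every stage is testable end to end.

## Worked example

```python
import gpcrbias as g

# simulate a wildtype-like cAMP panel, noiseless
truths = [g.GroundTruth(ligand="GLP-1",         log_tau=1.22, log_KA=-8.35),
          g.GroundTruth(ligand="oxyntomodulin", log_tau=0.92, log_KA=-7.44),
          g.GroundTruth(ligand="exendin-4",     log_tau=1.33, log_KA=-9.24)]
curves = []
for t in truths:
    center = -(t.log_KA) + __import__("numpy").log10(1 + 10**t.log_tau)
    design = g.AssayDesign(g.default_concentrations(center), noise_sd=0.0)
    curves.append(g.simulate_response_curve(t, design))

ops = g.fit_operational(curves, em=100.0)
f = ops["GLP-1"]
print(f.log_tau, f.log_KA, g.render_linear(f.log_tau))
```

prints

```
1.2200000000000004 -8.35 17
```

i.e. the generator's efficacy (log τ = 1.22, linear τ ≈ 17 — a strong
agonist whose plateau sits at 94% of the system maximum) and functional
affinity (K_A = 10^−8.35 M) are recovered exactly from noiseless data.
The full pipeline — logistic fits, binding pK_i, transduction
coefficients, bias factors and Dunnett statistics for the whole
13-receptor panel — runs from one call:

```python
results = g.run_pipeline(g.RunConfig(seed=1, output_dir="out"))
```

or from the shell: `gpcrbias all --seed 1 --out out` (see `gpcrbias
--help` for the per-stage subcommands `simulate`, `fit-logistic`,
`fit-binding`, `fit-operational`, `bias`, `stats`, `report`).

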