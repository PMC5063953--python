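"""Reference pharmacology panel for the human GLP-1R mutant study system.

The package's worked examples and default synthetic ground truth are built
around a published-scale characterization of the human glucagon-like
peptide-1 receptor (GLP-1R, a class B GPCR): the wildtype receptor plus
twelve alanine mutants of conserved polar residues at the transmembrane
helix boundaries (class-B residue numbering, e.g. ``R3.30A``), probed with
three peptide agonists — GLP-1(7-36)NH2, oxyntomodulin and exendin-4 —
plus the antagonist exendin-4(9-39), across three signalling endpoints
(cAMP accumulation, ERK1/2 phosphorylation, intracellular Ca2+
mobilisation).

Stored quantities, each as ``(mean, sem)`` with ``None`` for values that
could not be experimentally defined (ND):

* ``AFFINITY`` — whole-cell competition-binding pKi per ligand, plus cell
  surface expression (% of wildtype) by ELISA and by Bmax.
* ``LOG_TAU_C`` — operational efficacy log10 tau corrected to wildtype
  cell-surface expression, per pathway x agonist.
* ``NEG_LOG_KA`` — operational functional affinity, -log10 K_A (M).
* ``DELTA_DELTA_LOG_R`` — between-pathway bias factors
  DDlog(tau_c/K_A) relative to wildtype, per pathway pair x agonist.

These tables serve two roles: ground truth for the synthetic-data
generator (so recovery tests run at realistic parameter values) and input
for the desk-scale consistency checks (fold changes between pKi values,
antilog rendering of log-scale entries).
"""

from __future__ import annotations

import pandas as pd

WILDTYPE = "wildtype"

RECEPTORS = [
    WILDTYPE, "R2.46A", "N2.52A", "R3.30A", "Y3.53A", "K4.64A", "R5.40A",
    "R5.56A", "K6.35A", "R6.37A", "K6.40A", "E7.63A", "Q7.65A",
]

AGONISTS = ["GLP-1", "oxyntomodulin", "exendin-4"]
ANTAGONIST = "exendin-4(9-39)"
LIGANDS = AGONISTS + [ANTAGONIST]

PATHWAYS = ["cAMP", "pERK", "iCa"]

#: Pathway pairs used for bias factors, in reporting order.
PATHWAY_PAIRS = [("pERK", "cAMP"), ("pERK", "iCa"), ("iCa", "cAMP")]

#: Radiotracer used in competition binding: 0.05 nM of the labelled
#: antagonist exendin-4(9-39); its affinity at each construct is taken from
#: that construct's unlabelled exendin-4(9-39) pKi.
TRACER_CONC_M = 0.05e-9
TRACER_LIGAND = ANTAGONIST

ND = None

# pKi per ligand (GLP-1, oxyntomodulin, exendin-4, exendin-4(9-39)) and
# cell-surface expression (% wildtype) by ELISA and Bmax.
AFFINITY = {
    WILDTYPE: {"GLP-1": (8.67, 0.05), "oxyntomodulin": (7.26, 0.04),
               "exendin-4": (8.87, 0.04), ANTAGONIST: (8.11, 0.04),
               "elisa": (100, 1), "bmax": (100, 2)},
    "R2.46A": {"GLP-1": (8.40, 0.07), "oxyntomodulin": (7.28, 0.08),
               "exendin-4": (8.61, 0.11), ANTAGONIST: (8.17, 0.08),
               "elisa": (66, 2), "bmax": (72, 1)},
    "N2.52A": {"GLP-1": ND, "oxyntomodulin": ND, "exendin-4": ND,
               ANTAGONIST: ND, "elisa": (39, 5), "bmax": ND},
    "R3.30A": {"GLP-1": (7.41, 0.08), "oxyntomodulin": (6.69, 0.12),
               "exendin-4": (7.60, 0.09), ANTAGONIST: (8.52, 0.08),
               "elisa": (95, 4), "bmax": (83, 2)},
    "Y3.53A": {"GLP-1": (8.49, 0.09), "oxyntomodulin": (6.99, 0.24),
               "exendin-4": (8.68, 0.23), ANTAGONIST: (7.94, 0.06),
               "elisa": (82, 8), "bmax": (97, 4)},
    "K4.64A": {"GLP-1": (6.90, 0.08), "oxyntomodulin": (6.29, 0.07),
               "exendin-4": (7.39, 0.05), ANTAGONIST: (8.16, 0.05),
               "elisa": (107, 3), "bmax": (116, 2)},
    "R5.40A": {"GLP-1": (7.45, 0.12), "oxyntomodulin": (6.11, 0.08),
               "exendin-4": (7.99, 0.11), ANTAGONIST: (7.87, 0.14),
               "elisa": (40, 8), "bmax": (23, 3)},
    "R5.56A": {"GLP-1": (8.51, 0.09), "oxyntomodulin": (7.22, 0.06),
               "exendin-4": (8.59, 0.07), ANTAGONIST: (8.09, 0.08),
               "elisa": (112, 10), "bmax": (141, 3)},
    "K6.35A": {"GLP-1": (9.20, 0.07), "oxyntomodulin": (7.68, 0.05),
               "exendin-4": (9.34, 0.06), ANTAGONIST: (8.37, 0.04),
               "elisa": (175, 13), "bmax": (159, 5)},
    "R6.37A": {"GLP-1": (8.38, 0.08), "oxyntomodulin": (7.21, 0.08),
               "exendin-4": (8.80, 0.08), ANTAGONIST: (7.98, 0.08),
               "elisa": (57, 4), "bmax": (60, 1)},
    "K6.40A": {"GLP-1": (8.39, 0.07), "oxyntomodulin": (7.25, 0.14),
               "exendin-4": (8.92, 0.06), ANTAGONIST: (7.76, 0.08),
               "elisa": (81, 3), "bmax": (76, 2)},
    "E7.63A": {"GLP-1": (8.62, 0.12), "oxyntomodulin": (7.34, 0.09),
               "exendin-4": (8.29, 0.11), ANTAGONIST: (8.12, 0.07),
               "elisa": (59, 5), "bmax": (45, 4)},
    "Q7.65A": {"GLP-1": (8.72, 0.09), "oxyntomodulin": (7.22, 0.05),
               "exendin-4": (9.08, 0.09), ANTAGONIST: (8.39, 0.06),
               "elisa": (71, 5), "bmax": (78, 7)},
}

# Expression-corrected operational efficacy, log10 tau_c, keyed
# [receptor][pathway][agonist].
LOG_TAU_C = {
    WILDTYPE: {
        "cAMP": {"GLP-1": (1.22, 0.09), "oxyntomodulin": (0.92, 0.16), "exendin-4": (1.33, 0.15)},
        "pERK": {"GLP-1": (-0.08, 0.03), "oxyntomodulin": (-0.07, 0.03), "exendin-4": (-0.09, 0.03)},
        "iCa": {"GLP-1": (-0.30, 0.04), "oxyntomodulin": (-0.31, 0.02), "exendin-4": (-0.31, 0.03)},
    },
    "R2.46A": {
        "cAMP": {"GLP-1": (0.72, 0.21), "oxyntomodulin": (0.49, 0.11), "exendin-4": (1.07, 0.07)},
        "pERK": {"GLP-1": (-0.29, 0.05), "oxyntomodulin": (-0.09, 0.06), "exendin-4": (-0.28, 0.05)},
        "iCa": {"GLP-1": (-0.58, 0.12), "oxyntomodulin": (-0.40, 0.08), "exendin-4": (-0.62, 0.13)},
    },
    "N2.52A": {
        "cAMP": {"GLP-1": (0.55, 0.07), "oxyntomodulin": (0.48, 0.07), "exendin-4": (0.55, 0.05)},
        "pERK": {"GLP-1": (-0.39, 0.09), "oxyntomodulin": (0.01, 0.09), "exendin-4": (0.20, 0.05)},
        "iCa": {"GLP-1": ND, "oxyntomodulin": ND, "exendin-4": ND},
    },
    "R3.30A": {
        "cAMP": {"GLP-1": (0.86, 0.17), "oxyntomodulin": (0.53, 0.12), "exendin-4": (1.22, 0.10)},
        "pERK": {"GLP-1": (0.02, 0.04), "oxyntomodulin": (0.09, 0.06), "exendin-4": (-0.22, 0.05)},
        "iCa": {"GLP-1": (-0.29, 0.07), "oxyntomodulin": (0.08, 0.04), "exendin-4": (-0.34, 0.06)},
    },
    "Y3.53A": {
        "cAMP": {"GLP-1": (1.13, 0.29), "oxyntomodulin": (0.93, 0.40), "exendin-4": (0.99, 0.20)},
        "pERK": {"GLP-1": (-1.23, 0.15), "oxyntomodulin": (-1.12, 0.16), "exendin-4": (-1.16, 0.12)},
        "iCa": {"GLP-1": ND, "oxyntomodulin": ND, "exendin-4": ND},
    },
    "K4.64A": {
        "cAMP": {"GLP-1": (-0.47, 0.08), "oxyntomodulin": (-0.32, 0.08), "exendin-4": (-0.28, 0.05)},
        "pERK": {"GLP-1": (-1.11, 0.14), "oxyntomodulin": (-1.22, 0.16), "exendin-4": (-0.96, 0.09)},
        "iCa": {"GLP-1": ND, "oxyntomodulin": (-0.40, 0.05), "exendin-4": ND},
    },
    "R5.40A": {
        "cAMP": {"GLP-1": (0.67, 0.09), "oxyntomodulin": (0.76, 0.06), "exendin-4": (0.75, 0.06)},
        "pERK": {"GLP-1": (-0.55, 0.15), "oxyntomodulin": (-0.27, 0.29), "exendin-4": (-0.85, 0.21)},
        "iCa": {"GLP-1": ND, "oxyntomodulin": ND, "exendin-4": ND},
    },
    "R5.56A": {
        "cAMP": {"GLP-1": (1.18, 0.10), "oxyntomodulin": (0.91, 0.14), "exendin-4": (1.12, 0.13)},
        "pERK": {"GLP-1": (-1.01, 0.10), "oxyntomodulin": (-0.07, 0.08), "exendin-4": (-0.44, 0.06)},
        "iCa": {"GLP-1": (-1.06, 0.17), "oxyntomodulin": ND, "exendin-4": (-1.09, 0.27)},
    },
    "K6.35A": {
        "cAMP": {"GLP-1": (1.99, 0.10), "oxyntomodulin": (1.81, 0.24), "exendin-4": (1.93, 0.37)},
        "pERK": {"GLP-1": (0.57, 0.09), "oxyntomodulin": (0.35, 0.06), "exendin-4": (0.68, 0.09)},
        "iCa": {"GLP-1": (0.50, 0.20), "oxyntomodulin": (0.32, 0.09), "exendin-4": (1.12, 0.21)},
    },
    "R6.37A": {
        "cAMP": {"GLP-1": (1.36, 0.19), "oxyntomodulin": (1.37, 0.35), "exendin-4": (1.19, 0.12)},
        "pERK": {"GLP-1": (0.12, 0.04), "oxyntomodulin": (0.20, 0.06), "exendin-4": (0.13, 0.05)},
        "iCa": {"GLP-1": (-0.94, 0.21), "oxyntomodulin": (-0.16, 0.08), "exendin-4": (-0.86, 0.04)},
    },
    "K6.40A": {
        "cAMP": {"GLP-1": (1.34, 0.10), "oxyntomodulin": (0.95, 0.17), "exendin-4": (1.38, 0.19)},
        "pERK": {"GLP-1": (-0.15, 0.04), "oxyntomodulin": (-0.82, 0.16), "exendin-4": (-0.69, 0.08)},
        "iCa": {"GLP-1": ND, "oxyntomodulin": (-0.47, 0.11), "exendin-4": (-1.02, 0.22)},
    },
    "E7.63A": {
        "cAMP": {"GLP-1": (0.44, 0.06), "oxyntomodulin": (0.58, 0.07), "exendin-4": (0.50, 0.05)},
        "pERK": {"GLP-1": (-0.19, 0.05), "oxyntomodulin": (-0.28, 0.07), "exendin-4": (-0.38, 0.05)},
        "iCa": {"GLP-1": (-0.23, 0.13), "oxyntomodulin": (-0.07, 0.06), "exendin-4": (-0.33, 0.10)},
    },
    "Q7.65A": {
        "cAMP": {"GLP-1": (0.97, 0.10), "oxyntomodulin": (0.67, 0.07), "exendin-4": (0.96, 0.11)},
        "pERK": {"GLP-1": (-0.47, 0.07), "oxyntomodulin": (-0.70, 0.19), "exendin-4": (-0.58, 0.09)},
        "iCa": {"GLP-1": ND, "oxyntomodulin": (-0.22, 0.05), "exendin-4": (-1.19, 0.17)},
    },
}

# Operational functional affinity, -log10 K_A, same keying.
NEG_LOG_KA = {
    WILDTYPE: {
        "cAMP": {"GLP-1": (8.35, 0.10), "oxyntomodulin": (7.44, 0.09), "exendin-4": (9.24, 0.10)},
        "pERK": {"GLP-1": (7.84, 0.11), "oxyntomodulin": (7.46, 0.08), "exendin-4": (8.31, 0.07)},
        "iCa": {"GLP-1": (7.32, 0.14), "oxyntomodulin": (7.23, 0.34), "exendin-4": (7.46, 0.05)},
    },
    "R2.46A": {
        "cAMP": {"GLP-1": (8.08, 0.22), "oxyntomodulin": (7.01, 0.10), "exendin-4": (8.95, 0.36)},
        "pERK": {"GLP-1": (7.75, 0.14), "oxyntomodulin": (7.39, 0.13), "exendin-4": (8.12, 0.09)},
        "iCa": {"GLP-1": (7.26, 0.13), "oxyntomodulin": (7.38, 0.04), "exendin-4": (7.39, 0.12)},
    },
    "N2.52A": {
        "cAMP": {"GLP-1": (8.50, 0.09), "oxyntomodulin": (7.13, 0.13), "exendin-4": (9.16, 0.18)},
        "pERK": {"GLP-1": (7.91, 0.13), "oxyntomodulin": (7.40, 0.12), "exendin-4": (8.21, 0.12)},
        "iCa": {"GLP-1": ND, "oxyntomodulin": ND, "exendin-4": ND},
    },
    "R3.30A": {
        "cAMP": {"GLP-1": (7.50, 0.27), "oxyntomodulin": (6.69, 0.22), "exendin-4": (8.13, 0.10)},
        "pERK": {"GLP-1": (6.81, 0.06), "oxyntomodulin": (6.81, 0.13), "exendin-4": (7.31, 0.05)},
        "iCa": {"GLP-1": (6.79, 0.21), "oxyntomodulin": (7.81, 0.24), "exendin-4": (6.82, 0.13)},
    },
    "Y3.53A": {
        "cAMP": {"GLP-1": (8.24, 0.10), "oxyntomodulin": (7.23, 0.22), "exendin-4": (9.37, 0.10)},
        "pERK": {"GLP-1": (7.70, 0.11), "oxyntomodulin": (7.11, 0.08), "exendin-4": (8.11, 0.19)},
        "iCa": {"GLP-1": ND, "oxyntomodulin": ND, "exendin-4": ND},
    },
    "K4.64A": {
        "cAMP": {"GLP-1": (6.91, 0.32), "oxyntomodulin": (6.29, 0.06), "exendin-4": (8.16, 0.23)},
        "pERK": {"GLP-1": (7.13, 0.40), "oxyntomodulin": (7.30, 0.38), "exendin-4": (7.01, 0.12)},
        "iCa": {"GLP-1": ND, "oxyntomodulin": (6.90, 0.17), "exendin-4": ND},
    },
    "R5.40A": {
        "cAMP": {"GLP-1": (7.52, 0.35), "oxyntomodulin": (6.07, 0.41), "exendin-4": (7.79, 0.30)},
        "pERK": {"GLP-1": (7.91, 0.15), "oxyntomodulin": (6.35, 0.35), "exendin-4": (7.53, 0.31)},
        "iCa": {"GLP-1": ND, "oxyntomodulin": ND, "exendin-4": ND},
    },
    "R5.56A": {
        "cAMP": {"GLP-1": (8.61, 0.13), "oxyntomodulin": (7.56, 0.17), "exendin-4": (9.22, 0.13)},
        "pERK": {"GLP-1": (7.83, 0.11), "oxyntomodulin": (7.10, 0.28), "exendin-4": (8.33, 0.41)},
        "iCa": {"GLP-1": (7.26, 0.17), "oxyntomodulin": ND, "exendin-4": (7.10, 0.19)},
    },
    "K6.35A": {
        "cAMP": {"GLP-1": (9.18, 0.19), "oxyntomodulin": (7.64, 0.07), "exendin-4": (9.91, 0.11)},
        "pERK": {"GLP-1": (8.32, 0.04), "oxyntomodulin": (7.68, 0.03), "exendin-4": (8.21, 0.07)},
        "iCa": {"GLP-1": (7.91, 0.15), "oxyntomodulin": (7.27, 0.16), "exendin-4": (7.78, 0.08)},
    },
    "R6.37A": {
        "cAMP": {"GLP-1": (8.53, 0.21), "oxyntomodulin": (7.43, 0.08), "exendin-4": (9.37, 0.10)},
        "pERK": {"GLP-1": (7.73, 0.12), "oxyntomodulin": (7.39, 0.17), "exendin-4": (8.35, 0.30)},
        "iCa": {"GLP-1": (7.50, 0.14), "oxyntomodulin": (7.01, 0.10), "exendin-4": (7.08, 0.09)},
    },
    "K6.40A": {
        "cAMP": {"GLP-1": (8.14, 0.23), "oxyntomodulin": (7.48, 0.10), "exendin-4": (9.31, 0.09)},
        "pERK": {"GLP-1": (7.80, 0.15), "oxyntomodulin": (7.51, 0.19), "exendin-4": (8.12, 0.19)},
        "iCa": {"GLP-1": ND, "oxyntomodulin": (7.40, 0.10), "exendin-4": (7.15, 0.21)},
    },
    "E7.63A": {
        "cAMP": {"GLP-1": (8.87, 0.18), "oxyntomodulin": (7.11, 0.11), "exendin-4": (8.89, 0.18)},
        "pERK": {"GLP-1": (7.81, 0.09), "oxyntomodulin": (7.02, 0.19), "exendin-4": (8.35, 0.27)},
        "iCa": {"GLP-1": (7.16, 0.21), "oxyntomodulin": (6.91, 0.23), "exendin-4": (7.01, 0.09)},
    },
    "Q7.65A": {
        "cAMP": {"GLP-1": (8.01, 0.31), "oxyntomodulin": (6.99, 0.33), "exendin-4": (9.41, 0.11)},
        "pERK": {"GLP-1": (7.70, 0.18), "oxyntomodulin": (7.33, 0.23), "exendin-4": (8.35, 0.27)},
        "iCa": {"GLP-1": ND, "oxyntomodulin": (7.25, 0.15), "exendin-4": (7.10, 0.30)},
    },
}

# Bias factors DDlog(tau_c/K_A) relative to wildtype, keyed
# [receptor][(pathway1, pathway2)][agonist].
DELTA_DELTA_LOG_R = {
    WILDTYPE: {
        ("pERK", "cAMP"): {"GLP-1": (0.00, 0.12), "oxyntomodulin": (0.00, 0.07), "exendin-4": (0.00, 0.09)},
        ("pERK", "iCa"): {"GLP-1": (0.00, 0.11), "oxyntomodulin": (0.00, 0.10), "exendin-4": (0.00, 0.10)},
        ("iCa", "cAMP"): {"GLP-1": (0.00, 0.13), "oxyntomodulin": (0.00, 0.15), "exendin-4": (0.00, 0.09)},
    },
    "R2.46A": {
        ("pERK", "cAMP"): {"GLP-1": (0.29, 0.15), "oxyntomodulin": (0.70, 0.15), "exendin-4": (0.37, 0.16)},
        ("pERK", "iCa"): {"GLP-1": (0.29, 0.29), "oxyntomodulin": (-0.24, 0.33), "exendin-4": (0.57, 0.31)},
        ("iCa", "cAMP"): {"GLP-1": (0.57, 0.32), "oxyntomodulin": (0.52, 0.33), "exendin-4": (-0.21, 0.31)},
    },
    "N2.52A": {
        ("pERK", "cAMP"): {"GLP-1": (0.31, 0.32), "oxyntomodulin": (0.86, 0.21), "exendin-4": (0.99, 0.20)},
        ("pERK", "iCa"): {"GLP-1": ND, "oxyntomodulin": ND, "exendin-4": ND},
        ("iCa", "cAMP"): {"GLP-1": ND, "oxyntomodulin": ND, "exendin-4": ND},
    },
    "R3.30A": {
        ("pERK", "cAMP"): {"GLP-1": (0.52, 0.24), "oxyntomodulin": (0.97, 0.12), "exendin-4": (0.25, 0.17)},
        ("pERK", "iCa"): {"GLP-1": (0.26, 0.17), "oxyntomodulin": (-1.06, 0.15), "exendin-4": (0.24, 0.18)},
        ("iCa", "cAMP"): {"GLP-1": (0.86, 0.26), "oxyntomodulin": (0.81, 0.17), "exendin-4": (0.52, 0.14)},
    },
    "Y3.53A": {
        ("pERK", "cAMP"): {"GLP-1": (-0.94, 0.39), "oxyntomodulin": (-1.13, 0.36), "exendin-4": (-0.44, 0.30)},
        ("pERK", "iCa"): {"GLP-1": ND, "oxyntomodulin": ND, "exendin-4": ND},
        ("iCa", "cAMP"): {"GLP-1": ND, "oxyntomodulin": ND, "exendin-4": ND},
    },
    "K4.64A": {
        ("pERK", "cAMP"): {"GLP-1": (0.69, 0.32), "oxyntomodulin": (0.68, 0.37), "exendin-4": (1.17, 0.12)},
        ("pERK", "iCa"): {"GLP-1": ND, "oxyntomodulin": (-0.80, 0.28), "exendin-4": ND},
        ("iCa", "cAMP"): {"GLP-1": ND, "oxyntomodulin": (1.17, 0.32), "exendin-4": ND},
    },
    "R5.40A": {
        ("pERK", "cAMP"): {"GLP-1": (1.04, 0.41), "oxyntomodulin": (0.65, 0.33), "exendin-4": (0.96, 0.49)},
        ("pERK", "iCa"): {"GLP-1": ND, "oxyntomodulin": ND, "exendin-4": ND},
        ("iCa", "cAMP"): {"GLP-1": ND, "oxyntomodulin": ND, "exendin-4": ND},
    },
    "R5.56A": {
        ("pERK", "cAMP"): {"GLP-1": (-1.03, 0.23), "oxyntomodulin": (0.49, 0.16), "exendin-4": (-0.02, 0.17)},
        ("pERK", "iCa"): {"GLP-1": (-0.19, 0.35), "oxyntomodulin": ND, "exendin-4": (0.67, 0.57)},
        ("iCa", "cAMP"): {"GLP-1": (-0.83, 0.18), "oxyntomodulin": ND, "exendin-4": (-0.50, 0.35)},
    },
    "K6.35A": {
        ("pERK", "cAMP"): {"GLP-1": (-0.51, 0.26), "oxyntomodulin": (-0.65, 0.26), "exendin-4": (-0.38, 0.11)},
        ("pERK", "iCa"): {"GLP-1": (-0.56, 0.23), "oxyntomodulin": (0.08, 0.24), "exendin-4": (-0.82, 0.07)},
        ("iCa", "cAMP"): {"GLP-1": (-0.66, 0.13), "oxyntomodulin": (-1.54, 0.11), "exendin-4": (0.37, 0.10)},
    },
    "R6.37A": {
        ("pERK", "cAMP"): {"GLP-1": (-0.16, 0.16), "oxyntomodulin": (0.49, 0.13), "exendin-4": (0.49, 0.14)},
        ("pERK", "iCa"): {"GLP-1": (1.38, 0.36), "oxyntomodulin": (0.61, 0.24), "exendin-4": (0.84, 0.09)},
        ("iCa", "cAMP"): {"GLP-1": (-1.40, 0.25), "oxyntomodulin": (-0.11, 0.23), "exendin-4": (-0.25, 0.29)},
    },
    "K6.40A": {
        ("pERK", "cAMP"): {"GLP-1": (-0.19, 0.21), "oxyntomodulin": (-1.18, 0.28), "exendin-4": (-0.51, 0.24)},
        ("pERK", "iCa"): {"GLP-1": ND, "oxyntomodulin": (-1.07, 0.18), "exendin-4": (0.10, 0.24)},
        ("iCa", "cAMP"): {"GLP-1": ND, "oxyntomodulin": (-0.24, 0.29), "exendin-4": (-1.08, 0.21)},
    },
    "E7.63A": {
        ("pERK", "cAMP"): {"GLP-1": (0.80, 0.27), "oxyntomodulin": (0.36, 0.21), "exendin-4": (0.64, 0.22)},
        ("pERK", "iCa"): {"GLP-1": (0.15, 0.33), "oxyntomodulin": (-0.54, 0.27), "exendin-4": (-0.30, 0.29)},
        ("iCa", "cAMP"): {"GLP-1": (0.90, 0.15), "oxyntomodulin": (0.70, 0.24), "exendin-4": (0.88, 0.29)},
    },
    "Q7.65A": {
        ("pERK", "cAMP"): {"GLP-1": (-0.37, 0.10), "oxyntomodulin": (-0.48, 0.44), "exendin-4": (-0.10, 0.25)},
        ("pERK", "iCa"): {"GLP-1": ND, "oxyntomodulin": (-1.07, 0.48), "exendin-4": (0.90, 0.54)},
        ("iCa", "cAMP"): {"GLP-1": ND, "oxyntomodulin": (0.47, 0.18), "exendin-4": (-1.24, 0.52)},
    },
}


def affinity_table() -> pd.DataFrame:
    """Reference pKi and expression as a tidy DataFrame.

    One row per receptor x quantity, columns ``receptor, quantity, value,
    sem``; ND rows carry NaN.
    """
    rows = []
    for rec in RECEPTORS:
        for key, entry in AFFINITY[rec].items():
            v, s = entry if entry is not None else (float("nan"), float("nan"))
            rows.append({"receptor": rec, "quantity": key, "value": v, "sem": s})
    return pd.DataFrame(rows)


def _tidy(table: dict, value_name: str) -> pd.DataFrame:
    rows = []
    for rec in RECEPTORS:
        for pw, per_lig in table[rec].items():
            for lig, entry in per_lig.items():
                v, s = entry if entry is not None else (float("nan"), float("nan"))
                rows.append({"receptor": rec, "pathway": pw, "ligand": lig,
                             value_name: v, "sem": s, "nd": entry is None})
    return pd.DataFrame(rows)


def log_tau_c_table() -> pd.DataFrame:
    """Reference expression-corrected log tau_c, tidy long format."""
    return _tidy(LOG_TAU_C, "log_tau_c")


def neg_log_ka_table() -> pd.DataFrame:
    """Reference -log10 K_A, tidy long format."""
    return _tidy(NEG_LOG_KA, "neg_log_ka")


def bias_table() -> pd.DataFrame:
    """Reference between-pathway bias factors, tidy long format."""
    rows = []
    for rec in RECEPTORS:
        for (p1, p2), per_lig in DELTA_DELTA_LOG_R[rec].items():
            for lig, entry in per_lig.items():
                v, s = entry if entry is not None else (float("nan"), float("nan"))
                rows.append({"receptor": rec, "pathway1": p1, "pathway2": p2,
                             "ligand": lig, "ddlog_r": v, "sem": s,
                             "nd": entry is None})
    return pd.DataFrame(rows)


def expression_pct(receptor: str) -> float:
    """ELISA cell-surface expression (% of wildtype) for a construct."""
    entry = AFFINITY[receptor]["elisa"]
    if entry is None:
        raise ValueError(f"no ELISA expression recorded for {receptor!r}")
    return float(entry[0])


def ground_truth_panel() -> pd.DataFrame:
    """Ground-truth operational parameters for the synthetic full panel.

    Converts the expression-corrected reference efficacies back to raw
    log tau (log tau = log tau_c - log10(100/expression%)), pairs them with
    the reference -log10 K_A, and attaches binding pKi and expression so the
    whole study design can be simulated from one table. Pathway entries that
    were experimentally undefined (ND) keep NaN log_tau and are simulated as
    signal-free curves.

    Columns: receptor, ligand, pathway, log_tau, log_KA (log10 M), E_m,
    basal, slope_n, expression_pct, pKi.
    """
    import numpy as np

    rows = []
    for rec in RECEPTORS:
        expr = expression_pct(rec)
        shift = np.log10(100.0 / expr)
        for pw in PATHWAYS:
            for lig in AGONISTS:
                tc = LOG_TAU_C[rec][pw][lig]
                ka = NEG_LOG_KA[rec][pw][lig]
                nd = tc is None or ka is None
                pki = AFFINITY[rec][lig]
                rows.append({
                    "receptor": rec, "ligand": lig, "pathway": pw,
                    "log_tau": np.nan if nd else tc[0] - shift,
                    "log_KA": np.nan if nd else -ka[0],
                    "E_m": 100.0, "basal": 0.0, "slope_n": 1.0,
                    "expression_pct": expr,
                    "pKi": np.nan if pki is None else pki[0],
                })
    return pd.DataFrame(rows)
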