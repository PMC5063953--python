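import numpy as np
import pytest

import gpcrbias as g


@pytest.fixture(scope="session")
def wt_camp_truth():
    """Wildtype-like cAMP ground truth: a strong agonist panel with unit
    transducer slope on the %-of-system-max scale."""
    return [
        g.GroundTruth(ligand="GLP-1", pathway="cAMP", log_tau=1.22, log_KA=-8.35),
        g.GroundTruth(ligand="oxyntomodulin", pathway="cAMP", log_tau=0.92, log_KA=-7.44),
        g.GroundTruth(ligand="exendin-4", pathway="cAMP", log_tau=1.33, log_KA=-9.24),
    ]


def curves_for(truths, noise_sd=0.0, n_experiments=1, seed=0, n_conc=9):
    """Simulate one curve per ground truth, each on a grid centred on its
    own expected midpoint."""
    out = []
    for t in truths:
        tau = 10.0 ** t.log_tau
        center = -np.log10(10.0 ** t.log_KA / (1.0 + tau))
        design = g.AssayDesign(g.default_concentrations(center, n=n_conc),
                               n_experiments=n_experiments,
                               noise_sd=noise_sd, seed=seed)
        out.append(g.simulate_response_curve(t, design))
    return out


@pytest.fixture(scope="session")
def wt_camp_noiseless(wt_camp_truth):
    return curves_for(wt_camp_truth)
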