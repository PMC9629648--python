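"""Perturbational complexity index after non-sustained local forcing.

Pairs of homotopic nodes are forced for the first part of the run; the
signal after forcing offset is z-scored against matched unperturbed
runs, binarized at z > 2, and scored by entropy-normalized Lempel-Ziv
complexity. PCI = perturbed complexity minus background complexity:
negative values mean the echo of the stimulus leaves structured
(compressible) activity, i.e. a strong response.
"""

import numpy as np

from hopfpert import homotopic_pairs
from hopfpert.perturbation import run_pci_protocol
from hopfpert.simulator import ModelParams
from hopfpert.synthetic import SyntheticSpec, make_coupling, make_parcellation

spec = SyntheticSpec(seed=42)
parc = make_parcellation(spec)
coupling = make_coupling(spec, parc)
omega = spec.draw_omega(np.random.default_rng(0))
pairs = homotopic_pairs(parc)[:4]
F0 = [0.0, 0.01, 0.02]

for label, (a, G, beta) in {
    "subcritical": (-0.02, 2.2, 0.0),
    "oscillatory": (1.3, 0.4, 2.2),
}.items():
    params = ModelParams(a=a, omega=omega, G=G, beta=beta, nu=0.01)
    res = run_pci_protocol(params, coupling, pairs, F0, n_sims=4, seed=9,
                           n_on=150, n_off=100)
    print(f"{label}: mean |PCI| per F0 {F0} = "
          f"{np.abs(res.pci).mean(axis=0).round(4)}")
# In the oscillatory regime the post-stimulus signal never crosses the
# z = 2 threshold (a z-scored oscillation peaks near sqrt(2)), so both
# complexities vanish and PCI stays 0: the stimulus leaves no trace.
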