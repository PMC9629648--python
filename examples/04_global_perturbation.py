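"""Global strength-dependent perturbation of two fitted regimes.

All 68 nodes are forced at their intrinsic frequency with amplitudes
F0 = 0 .. 0.001. Susceptibility (mean shift of the global order
parameter against seed-paired unperturbed runs) rises steeply and
monotonically with F0 in the subcritical fluctuating regime; the
oscillatory regime's response carries no comparable trend, only
realization-dependent phase shifts — the strength-dependent contrast
that separates two regimes which fit resting data equally well.
"""

import numpy as np

from hopfpert.perturbation import run_global_protocol
from hopfpert.simulator import ModelParams
from hopfpert.synthetic import SyntheticSpec, make_coupling, make_parcellation

spec = SyntheticSpec(seed=42)
parc = make_parcellation(spec)
coupling = make_coupling(spec, parc)
omega = spec.draw_omega(np.random.default_rng(0))
F0 = np.round(np.arange(0.0, 0.00101, 0.0001), 6)

for label, (a, G, beta) in {
    "subcritical": (-0.02, 2.2, 0.0),
    "oscillatory": (1.3, 0.4, 2.2),
}.items():
    params = ModelParams(a=a, omega=omega, G=G, beta=beta, nu=0.01,
                         n_volumes=200)
    resp = run_global_protocol(params, coupling, F0, reps=1,
                               n_trials=5, n_sims=4, seed=3)
    chi = ", ".join(f"{c:+.3f}" for c in resp.chi[::2])
    print(f"{label}: chi(F0 = 0, 2e-4, .., 1e-3) = [{chi}]")
    print(f"  max |chi| = {np.abs(resp.chi).max():.4f}, "
          f"max IC_abs = {resp.ic_abs.max():.4f}")
# chi(0) is exactly 0 by the paired-seed construction.
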