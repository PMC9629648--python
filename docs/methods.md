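# Methods

## Model

Each brain region `i` is a Stuart-Landau oscillator — the normal form of
a supercritical Hopf bifurcation with shear — coupled diffusively
through a structural matrix and driven by additive Gaussian noise:

    dz_i/dt = (a_i + i ω_i) z_i − (1 + i β) z_i |z_i|²
              + G Σ_j C_ij (z_j − z_i) + F_i(t) + ν η_i(t),

written and integrated in Cartesian coordinates (z = x + iy); x = Re z
is the simulated BOLD signal. The bifurcation parameter selects the
regime: `a ≪ 0` is a noise regime (fast damped fluctuations), `a` just
below 0 a subcritical fluctuating regime, `a > 0` a supercritical
oscillatory regime on the limit cycle r = √a. The shear
(nonisochronicity) β couples amplitude to phase velocity
(θ̇ = ω − β r² on the cycle) and prevents full synchronization of the
coupled system, playing the role of viscosity in the turbulence
analogy. The external perturbation is an additive periodic force
F_i = F0_i [cos(ω_i t) + i sin(ω_i t)] at the node's intrinsic
frequency (configurable), applied globally, or to homotopic node pairs.

A note on signs: expanding the normal form gives `+ω x` in the
imaginary-part equation; the package uses the normal-form signs
throughout, which is what the rotation-rate identity θ̇ = ω − β r²
(used as a test oracle) requires.

## Coupling

The default coupling is the exponential distance rule,
C_ij = exp(−λ r_ij) with λ = 0.18 mm⁻¹ and r_ij the Euclidean distance
between region centroids, optionally augmented by long-range
connections taken from a structural-connectivity matrix (EDR-LR).
Because published work does not pin down the long-range extraction
rule, the rule is a pluggable object; the default keeps the top-K
positive residuals of the SC over its own fitted exponential
distance-weight relation (K = N), and a plain distance-threshold rule
is provided. Tractography matrices are symmetrized by the arithmetic
mean and rescaled to a maximum of 0.2.

## Observables

BOLD series are band-passed to 0.008–0.08 Hz with a 2nd-order
zero-phase Butterworth filter, and phases φ_p(t) taken from the
analytic signal; 10 volumes are trimmed at each end. The local
Kuramoto order parameter weights neighbour phase factors by the pure
EDR kernel *including* the unit self term exp(0) = 1 (each node
participates in its own neighbourhood — required, e.g., for an
equal-weight antiphase pair to cancel to R = 0). Amplitude turbulence
D is the SD of R_n(t) pooled over space and time; metastability M is
the SD over time of the global order parameter gR(t). Fit errors are
eD = |D_sim − D_emp| and eM = |M_sim − M_emp|. FC is Pearson
correlation over node pairs; FC agreement is reported as the
root-mean-square difference of upper-triangle vectors (the raw
Euclidean norm is also kept), the Pearson correlation of upper
triangles, and a single global SSIM with the conventional stabilizing
constants on matrices jointly rescaled to [0, 1].

## Numerics

The integrator uses integer substepping so the output interval
TR = 0.72 s is an exact multiple of the step. The default scheme is
stochastic Heun (trapezoidal drift, additive noise entering the
predictor) at dt = 0.1 s. Plain Euler-Maruyama is available
(`scheme="euler"`) but leaves an O(dt) bias in the stationary
fluctuation amplitude — the discrete Ornstein-Uhlenbeck variance
ν²h/(1−(1+ah)²) exceeds ν²/(2|a|) by a factor ≈ 1+|a|h — which at
dt = 0.1 amounts to ~3% and fails a 2% step-halving robustness check;
Heun's trapezoidal treatment of the increment removes the O(h) term
(measured halving gap ~0.2%). Forward stepping of the sheared limit
cycle is linearly unstable when dt ≳ 1/(a(1+β²)); the step is capped
automatically at one fifth of that bound, so supercritical runs with
large β take proportionally more substeps. A guard aborts with node
and volume indices when |z| exceeds 10·max(1, √a). Initial conditions
are uniform in [−0.1, 0.1]; 20 transient volumes are discarded. Noise
is injected independently in x and y by default (the equations print
one symbol for both; a shared-stream switch exists). The noise SD
defaults to ν = 0.01, the value standard in Hopf whole-brain models.

## Fitting

The (G, β) plane is explored exhaustively per regime; the optimal
working point minimizes the turbulence error (fine mode) or the
metastability error (coarse mode) — never the FC error, which is
reported alongside. Published grids are shipped as presets. Per-cell
seeds derive from the master seed by a counter scheme
(SeedSequence([master, cell_i, cell_j, sim])), so enlarging a grid
never changes existing cells. Divergent cells are excluded from the
argmin with a warning; exact ties break lexicographically toward lower
G then lower β. Node frequencies can be resampled per simulation via
`omega_sampler`, mirroring cohort-to-cohort frequency variability.
Regime comparison runs `n_trials` trials of `n_sims` simulations and
applies two-sided Wilcoxon rank-sum tests to the trial means;
β-inflated surrogate models (β → 6 at fine scale, 3 at coarse scale)
act as negative controls.

## Perturbation readouts

All protocols use a paired-seed design: each perturbed run shares its
noise realization with an unperturbed partner, so every readout is
exactly zero at F0 = 0 by construction. Susceptibility is the time
mean of the order-parameter shift, averaged over simulations, then
trials (then space for the local observable). Information capability
is the SD across trials of the per-trial mean shift — population SD by
default (`ddof=0`), switchable — with the absolute IC referenced to the
zero-forcing value computed from the same seeds. The global protocol
forces all nodes over F0 = 0…0.001 (step 1e-4); the local protocol
forces homotopic pairs over F0 = 0…0.02 with step 0.001 by default
(a 0.005-step preset also exists, matching a published variant of the
same protocol).

PCI: runs of n_on + n_off volumes (published lengths 600 + 200) are
forced for the first n_on volumes; the post-offset window is z-scored
node-wise against the matched unperturbed run's window, binarized at
z > 2, flattened node-major, and scored by Lempel-Ziv (LZ76,
exhaustive-production counting) complexity normalized as
c̄ = c·log₂L/(L·H(L)) with H the binary entropy of the fraction of
ones, so an i.i.d. fair-coin sequence scores ≈ 1 and a constant
sequence is defined as 0. PCI = c̄ − c̄_back, with the background from
the unperturbed window binarized against its own statistics. Negative
PCI means the stimulus echo leaves structured, compressible activity —
the signature of a strong response. A z-scored pure oscillation never
crosses z = 2 (its peak z is √2), so the oscillatory regime yields
c̄ = c̄_back = 0 and PCI = 0: the stimulus leaves no trace, matching
the regime's unresponsiveness in the other readouts.

## Synthetic data

The generator emulates the study inputs: N/2 centroids on a 70 mm
hemispheric shell mirrored into exact homotopic pairs (|x| bounded
away from the midline); seven network labels from k-means on
midline-folded coordinates so partners share a network; EDR coupling
plus `n_long_range` random long-range additions among
top-distance-quartile pairs (weights ≤ 0.2); per-subject node
frequencies ~ N(0.05 Hz, 0.005 Hz) clipped to the band; heterogeneity
maps as distance-kernel-smoothed Gaussian fields blended with the
structural strength map at a chosen correlation (the structural
component is projected out of the noise part, so the correlation
parameter is exact in expectation). It does not emulate hemodynamics,
empirical SC statistics beyond the EDR+LR structure, subject-level
head-motion or physiological artifacts — so green tests say the
machinery and the regime-contrast physics are right, not that real
fMRI would yield the same numbers.

Desk-scale defaults are N = 68, T = 400 volumes, 10 subjects, with
published-scale values (1200 volumes, larger simulation counts)
available as explicit arguments. The subcritical cohort default is
(a*, G*, β*) = (−0.02, 2.2, 0) — the coarse-scale fluctuating working
point.

## Identifiability and design choices in the validation experiments

Two desk-scale findings shape the validation suite, and are themselves
documented model behaviour rather than artifacts:

* **Shear is inert in sub-threshold regimes at this scale.** With
  diffusive coupling, x'(C − diag(rowsum))x ≤ 0, so the effective
  linear rate never exceeds `a`; for a < 0 amplitudes stay at the
  Ornstein-Uhlenbeck scale (mean |z|² ~ 1e-4 at ν = 0.01), making
  β·r² negligible against ω. Raising β therefore does not move D at
  the subcritical working point, and the β-inflated surrogate is
  statistically indistinguishable from it there (the corresponding
  validation test documents this by failing). At the oscillatory
  working point, where amplitudes are O(1), raising β *increases* the
  spatial variability D (partial desynchronization) rather than
  suppressing it; apparent suppression of the metastability M seen
  with coarser integration steps disappears under the accurate
  scheme. Suppression of synchronization variability by shear should
  therefore not be expected from this model at the 68-node scale and
  noise level.
* **The oscillatory regime is not quiet under forcing here.** At the
  coarse oscillatory working point (G = 0.4, β = 2.2) the synthetic
  network shows chaotic, itinerant partial synchronization: paired
  perturbed/unperturbed runs decorrelate, leaving an order-parameter
  difference floor (SD ≈ 0.12) that no desk-scale number of paired
  simulations averages below one tenth of the subcritical response.
  At the fine working points (weak coupling) the susceptibility floor
  shrinks but the across-trial response variance of the oscillators —
  realization-dependent phase shifts under resonant forcing — still
  exceeds the subcritical information capability, and this ratio is
  invariant to simulation counts. The regime-contrast validation
  therefore asserts the subcritical monotonicity and the PCI contrast
  (both hold), while its "oscillatory curves below 10% of
  subcritical" clause documents the discrepancy by failing.
* **A scalar fit error has ridge degeneracy.** eD (or eM) is one
  number against two parameters, so iso-level curves run through the
  (G, β) plane and a grid argmin wanders along them. The
  parameter-recovery experiment therefore places the ground truth at
  an extremum of the D landscape inside the searched grid (oscillatory
  regime, (G*, β*) = (1.0, 1.0), grid G ∈ 0.2…1.0, β ∈ 1…5), where
  the iso-set closes around the truth cell; recovery is then exact or
  within one step. Subcritical β is unidentifiable at desk scale for
  the reason above, and G only weakly so.

## Problem sizes

Validation runs use N = 68, 150–400 volumes and tens of simulations
per condition; the published protocol sizes (1200 volumes, 50×50 to
50×100 trial structures, 100-simulation PCI averages) are presets on
the same code paths. All randomness flows from a single master seed
through counter-based derivation.

## Known limitations

* The BOLD signal is the raw oscillator real part; no hemodynamic
  forward model.
* Windowed SSIM is out of scope; only the global index is computed.
* The LZ76 normalization uses the realized fraction of ones; for very
  sparse binarizations (z > 2 crossings) H(L) is small and c̄ is
  correspondingly noisy at short windows.
* The oscillatory regime's order-parameter time means carry slow
  itinerant fluctuations; paired differences there average slowly, so
  oscillatory susceptibility estimates need many more paired runs than
  subcritical ones for the same precision.
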