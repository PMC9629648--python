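"""Strength-dependent perturbation protocols and their readouts.

An external periodic force F_j = F0_j[cos(w_j t) + i sin(w_j t)] is added
to the node equations, either globally (all nodes) or locally (pairs of
homotopic nodes), at each node's intrinsic frequency by default. Three
readouts quantify the response:

* susceptibility chi: the mean shift of the (local or global) Kuramoto
  order parameter between perturbed and unperturbed runs sharing the
  same noise realization (paired design);
* information capability IC: the across-trial standard deviation of that
  shift; the absolute IC references each forcing strength to zero
  forcing;
* PCI: a BOLD-adapted perturbational complexity index — the normalized
  Lempel-Ziv complexity of the binarized post-stimulus activity minus
  the matched unperturbed background complexity.

Because perturbed and unperturbed runs share seeds, all three measures
are exactly zero at F0 = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import observables as obs
from .fitting import derive_seed
from .simulator import DivergenceError, ForcingSpec, ModelParams, simulate

__all__ = [
    "PairedSamples",
    "PerturbationResponse",
    "PCIResult",
    "paired_trials",
    "susceptibility",
    "information_capability",
    "run_global_protocol",
    "run_local_protocol",
    "lz76",
    "lz_complexity_normalized",
    "run_pci_protocol",
    "GLOBAL_F0_GRID",
    "LOCAL_F0_GRID",
    "LOCAL_F0_GRID_COARSE_STEP",
]

#: Global protocol forcing grid: 0 to 0.001 in steps of 0.0001.
GLOBAL_F0_GRID = np.round(np.arange(0.0, 0.00101, 0.0001), 6)
#: Local protocol forcing grid: 0 to 0.02 in steps of 0.001.
LOCAL_F0_GRID = np.round(np.arange(0.0, 0.0201, 0.001), 6)
#: Alternative local grid with the coarser 0.005 step.
LOCAL_F0_GRID_COARSE_STEP = np.round(np.arange(0.0, 0.0201, 0.005), 6)


@dataclass
class PairedSamples:
    """Per-(trial, sim) time-means of an order parameter, paired runs.

    ``perturbed`` and ``unperturbed`` have shape (n_trials, n_sims) for
    the global observable or (n_trials, n_sims, N) for the local one.
    """

    perturbed: np.ndarray
    unperturbed: np.ndarray
    observable: str
    n_excluded: int = 0

    @property
    def diff(self) -> np.ndarray:
        return self.perturbed - self.unperturbed

    @property
    def trial_means(self) -> np.ndarray:
        """Per-trial mean over simulations of the paired difference."""
        return np.nanmean(self.diff, axis=1)


@dataclass
class PerturbationResponse:
    """Susceptibility and absolute information capability vs forcing."""

    F0_values: np.ndarray
    chi: np.ndarray
    ic_abs: np.ndarray
    target: object = "global"
    chi_sd: np.ndarray | None = None
    ic_abs_sd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class PCIResult:
    """Per-(target pair, F0) perturbational complexity index."""

    pci: np.ndarray
    c_norm: np.ndarray
    c_back: np.ndarray
    F0_values: np.ndarray
    pairs: list
    z_threshold: float = 2.0


def _observable_timeseries(bold, TR, observable, edr_weights, band):
    ph = obs.bandpass_phase(bold, TR, band=band)
    if observable == "local":
        return obs.local_kuramoto(ph, edr_weights)  # (N, T')
    if observable == "global":
        return obs.global_kuramoto(ph)  # (T',)
    raise ValueError("observable must be 'local' or 'global'")


def paired_trials(
    params: ModelParams,
    coupling,
    forcing: ForcingSpec,
    n_trials: int,
    n_sims: int,
    seed: int = 0,
    observable: str = "global",
    edr_weights=None,
    band: tuple[float, float] = obs.DEFAULT_BAND,
    seed_key: tuple = (),
) -> PairedSamples:
    """Paired perturbed/unperturbed samples of an order parameter.

    For every (trial, sim) a perturbed and an unperturbed run share the
    same derived seed, so the noise realization is identical and the
    forcing is the only difference. Each sample is the time-mean of the
    global gR(t) (scalar) or of the local R_n(t) (per node). Divergent
    simulations are excluded (NaN) and counted.
    """
    if observable == "local" and edr_weights is None:
        raise ValueError("local observable needs the EDR local weights")
    if forcing.schedule == "off":
        forcing = ForcingSpec(forcing.F0, forcing.omega_forcing, "sustained")
    no_force = ForcingSpec(0.0, None, "off")
    shape = (n_trials, n_sims) + ((params.n_nodes,) if observable == "local" else ())
    pert = np.full(shape, np.nan)
    unpert = np.full(shape, np.nan)
    excluded = 0
    f0_arr, _ = forcing.resolve(params)
    forced = bool(np.any(f0_arr > 0))
    for t in range(n_trials):
        for s in range(n_sims):
            sub_seed = derive_seed(seed, *seed_key, t, s)
            try:
                base = simulate(params, coupling, no_force, seed=sub_seed)
                u = _observable_timeseries(
                    base.bold, params.TR, observable, edr_weights, band
                ).mean(axis=-1)
                if forced:
                    run = simulate(params, coupling, forcing, seed=sub_seed)
                    p = _observable_timeseries(
                        run.bold, params.TR, observable, edr_weights, band
                    ).mean(axis=-1)
                else:
                    p = u
            except DivergenceError:
                excluded += 1
                continue
            pert[t, s], unpert[t, s] = p, u
    return PairedSamples(pert, unpert, observable, n_excluded=excluded)


def susceptibility(samples: PairedSamples, spatial_mean: bool = True) -> float | np.ndarray:
    """Mean perturbed-minus-unperturbed order-parameter shift.

    Averaged over simulations then trials; the local observable is also
    averaged over space unless ``spatial_mean`` is False (per-node
    hierarchy use).
    """
    chi = np.nanmean(samples.trial_means, axis=0)
    if samples.observable == "local" and spatial_mean:
        return float(np.mean(chi))
    return float(chi) if np.ndim(chi) == 0 else chi


def information_capability(
    samples: PairedSamples, ddof: int = 0, spatial_mean: bool = True
) -> float | np.ndarray:
    """SD across trials of the per-trial mean order-parameter shift.

    Population SD by default (``ddof=0``); the local observable takes
    the per-node SD across trials and then averages over space.
    """
    tm = samples.trial_means  # (n_trials,) or (n_trials, N)
    ic = np.nanstd(tm, axis=0, ddof=ddof)
    if samples.observable == "local" and spatial_mean:
        return float(np.mean(ic))
    return float(ic) if np.ndim(ic) == 0 else ic


def run_global_protocol(
    params: ModelParams,
    coupling,
    F0_values=GLOBAL_F0_GRID,
    reps: int = 20,
    n_trials: int = 50,
    n_sims: int = 50,
    seed: int = 0,
    observable: str = "global",
    edr_weights=None,
    band: tuple[float, float] = obs.DEFAULT_BAND,
) -> PerturbationResponse:
    """Global sustained forcing of all nodes over a strength grid.

    All nodes are forced at their intrinsic frequency; chi and absolute
    IC are computed per forcing strength, with mean and SD over
    ``reps`` independent repetitions. Within a repetition the same
    seeds are reused across the F0 grid (common random numbers), so
    the zero-forcing reference is exact.
    """
    F0_values = np.asarray(F0_values, dtype=float)
    chi = np.empty((reps, F0_values.size))
    ic = np.empty((reps, F0_values.size))
    for r in range(reps):
        for k, f0 in enumerate(F0_values):
            forcing = ForcingSpec(F0=f0, schedule="sustained")
            samples = paired_trials(
                params, coupling, forcing, n_trials, n_sims,
                seed=seed, observable=observable, edr_weights=edr_weights,
                band=band, seed_key=(r,),
            )
            chi[r, k] = susceptibility(samples)
            ic[r, k] = information_capability(samples)
        # reference IC at zero forcing shares the repetition's seeds
        if 0.0 in F0_values:
            ic0 = ic[r, list(F0_values).index(0.0)]
        else:
            zero = paired_trials(
                params, coupling, ForcingSpec(0.0, None, "sustained"),
                n_trials, n_sims, seed=seed, observable=observable,
                edr_weights=edr_weights, band=band, seed_key=(r,),
            )
            ic0 = information_capability(zero)
        ic[r] = np.abs(ic[r] - ic0)
    return PerturbationResponse(
        F0_values=F0_values,
        chi=chi.mean(axis=0),
        ic_abs=ic.mean(axis=0),
        chi_sd=chi.std(axis=0),
        ic_abs_sd=ic.std(axis=0),
        target="global",
        meta={"reps": reps, "n_trials": n_trials, "n_sims": n_sims},
    )


def _pair_forcing(params: ModelParams, pair, f0: float) -> ForcingSpec:
    amp = np.zeros(params.n_nodes)
    amp[list(pair)] = f0
    return ForcingSpec(F0=amp, schedule="sustained")


def run_local_protocol(
    params: ModelParams,
    coupling,
    pairs,
    F0_values=LOCAL_F0_GRID,
    n_trials: int = 50,
    n_sims: int = 100,
    seed: int = 0,
    edr_weights=None,
    band: tuple[float, float] = obs.DEFAULT_BAND,
    reference_F0: float = 0.01,
) -> dict:
    """Sustained forcing of homotopic node pairs over a strength grid.

    Per pair and forcing strength, chi and absolute IC are computed on
    the global order parameter. The perturbative node hierarchy ranks
    pairs by susceptibility at ``reference_F0`` (nearest grid value).

    Returns a dict with per-pair :class:`PerturbationResponse` objects,
    the (pair, F0) chi and ic_abs surfaces, and the hierarchy order.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty homotopic pair list")
    F0_values = np.asarray(F0_values, dtype=float)
    chi = np.empty((len(pairs), F0_values.size))
    ic = np.empty((len(pairs), F0_values.size))
    responses = []
    for m, pair in enumerate(pairs):
        ic_row = np.empty(F0_values.size)
        for k, f0 in enumerate(F0_values):
            samples = paired_trials(
                params, coupling, _pair_forcing(params, pair, f0),
                n_trials, n_sims, seed=seed, observable="global",
                edr_weights=edr_weights, band=band, seed_key=(m,),
            )
            chi[m, k] = susceptibility(samples)
            ic_row[k] = information_capability(samples)
        if 0.0 in F0_values:
            ic0 = ic_row[list(F0_values).index(0.0)]
        else:
            zero = paired_trials(
                params, coupling, _pair_forcing(params, pair, 0.0),
                n_trials, n_sims, seed=seed, observable="global",
                edr_weights=edr_weights, band=band, seed_key=(m,),
            )
            ic0 = information_capability(zero)
        ic[m] = np.abs(ic_row - ic0)
        responses.append(
            PerturbationResponse(
                F0_values=F0_values, chi=chi[m], ic_abs=ic[m], target=tuple(pair)
            )
        )
    ref_idx = int(np.argmin(np.abs(F0_values - reference_F0)))
    hierarchy = np.argsort(chi[:, ref_idx])[::-1]
    return {
        "responses": responses,
        "chi": chi,
        "ic_abs": ic,
        "F0_values": F0_values,
        "pairs": pairs,
        "hierarchy": hierarchy,
        "reference_F0": float(F0_values[ref_idx]),
    }


def lz76(sequence: np.ndarray) -> int:
    """Lempel-Ziv (LZ76) complexity: number of exhaustive productions.

    Kaspar-Schuster counting over a binary sequence.
    """
    s = np.asarray(sequence).ravel()
    bits = s.astype(np.uint8)
    if not np.isin(bits, (0, 1)).all() or not np.array_equal(bits, s):
        raise ValueError("LZ76 requires a strictly binary sequence")
    b = bits.tobytes()
    n = len(b)
    if n == 0:
        return 0
    c = 0
    i = 0
    while i < n:
        # extend the current word while it can be copied from earlier
        # (the copy source may overlap the word itself, per LZ76)
        k = 1
        while i + k <= n and b.find(b[i: i + k], 0, i + k - 1) != -1:
            k += 1
        c += 1
        i += k
    return c


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log2(p) - (1 - p) * math.log2(1 - p)


def lz_complexity_normalized(binary: np.ndarray) -> float:
    """Entropy-normalized LZ76 complexity, ~1 for a fair-coin sequence.

    c_bar = c_L * log2(L) / (L * H(L)) with H the binary entropy of the
    sequence's fraction of ones. Matrices are flattened node-major then
    time (C order). An all-constant sequence is defined as 0.
    """
    s = np.asarray(binary)
    flat = s.ravel(order="C").astype(np.uint8)
    if not np.isin(flat, (0, 1)).all() or not np.array_equal(flat, s.ravel(order="C")):
        raise ValueError("binary input required")
    L = flat.size
    if L == 0:
        raise ValueError("empty sequence")
    H = _binary_entropy(float(flat.mean()))
    if H == 0.0:
        return 0.0
    return lz76(flat) * math.log2(L) / (L * H)


def run_pci_protocol(
    params: ModelParams,
    coupling,
    pairs,
    F0_values=LOCAL_F0_GRID,
    n_sims: int = 100,
    seed: int = 0,
    n_on: int = 600,
    n_off: int = 200,
    z_threshold: float = 2.0,
) -> PCIResult:
    """Non-sustained local forcing scored by perturbational complexity.

    Per pair, forcing strength and simulation: a run of n_on + n_off
    volumes is perturbed for the first n_on and free for the last n_off;
    a matched unperturbed run shares the seed. The post-perturbation
    window is z-scored node-wise against the matched unperturbed
    window's mean/SD, binarized at z > ``z_threshold``, and scored by
    normalized LZ76 complexity; the background complexity comes from the
    unperturbed window binarized the same way against its own stats.
    PCI(F0, pair) = mean over sims of (c_bar - c_bar_back).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty homotopic pair list")
    if n_on < 1 or n_off < 2:
        raise ValueError("need n_on >= 1 and n_off >= 2 volumes")
    run_params = params.replace(n_volumes=n_on + n_off)
    F0_values = np.asarray(F0_values, dtype=float)
    pci = np.zeros((len(pairs), F0_values.size))
    c_norm = np.zeros_like(pci)
    c_back = np.zeros_like(pci)
    no_force = ForcingSpec(0.0, None, "off")
    for m, pair in enumerate(pairs):
        for k, f0 in enumerate(F0_values):
            vals, backs = [], []
            for s in range(n_sims):
                sub_seed = derive_seed(seed, m, k, s)
                base = simulate(run_params, coupling, no_force, seed=sub_seed)
                bwin = base.bold[:, -n_off:]
                mu = bwin.mean(axis=1, keepdims=True)
                sd = bwin.std(axis=1, keepdims=True)
                sd[sd == 0] = 1.0
                back_bin = ((bwin - mu) / sd > z_threshold).astype(np.uint8)
                cb = lz_complexity_normalized(back_bin)
                if f0 > 0:
                    amp = np.zeros(run_params.n_nodes)
                    amp[list(pair)] = f0
                    forcing = ForcingSpec(
                        F0=amp, schedule=("on_then_off", n_on, n_off)
                    )
                    run = simulate(run_params, coupling, forcing, seed=sub_seed)
                    pwin = run.bold[:, -n_off:]
                    pert_bin = ((pwin - mu) / sd > z_threshold).astype(np.uint8)
                    cp = lz_complexity_normalized(pert_bin)
                else:
                    cp = cb
                vals.append(cp)
                backs.append(cb)
            c_norm[m, k] = float(np.mean(vals))
            c_back[m, k] = float(np.mean(backs))
            pci[m, k] = c_norm[m, k] - c_back[m, k]
    return PCIResult(
        pci=pci, c_norm=c_norm, c_back=c_back,
        F0_values=F0_values, pairs=pairs, z_threshold=z_threshold,
    )
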