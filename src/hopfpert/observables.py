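"""Fitting observables: phases, Kuramoto order parameters, turbulence,
metastability, functional connectivity and the scalar fit errors.

Phases come from a zero-phase band-pass (0.008-0.08 Hz) followed by the
analytic-signal angle. The local Kuramoto order parameter weights each
neighbour by the exponential distance rule and its modulus R_n(t)
measures local synchronization; amplitude turbulence D is the standard
deviation of R_n(t) pooled over space and time, and metastability M is
the standard deviation over time of the global order parameter gR(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import CouplingMatrix

__all__ = [
    "PhaseField",
    "FitErrors",
    "bandpass_phase",
    "local_kuramoto",
    "amplitude_turbulence",
    "global_kuramoto",
    "metastability",
    "functional_connectivity",
    "fc_metrics",
    "turbulence_error",
    "metastability_error",
    "DEFAULT_BAND",
]

#: Band used to transform BOLD into phase space, Hz.
DEFAULT_BAND = (0.008, 0.08)


@dataclass
class PhaseField:
    """Instantaneous phases of band-limited signals."""

    phases: np.ndarray
    filtered: np.ndarray
    band: tuple[float, float]
    edge_trim: int


@dataclass
class FitErrors:
    """Scalar fit errors between simulated and empirical observables."""

    eD: float | None = None
    eM: float | None = None
    eFC: float | None = None
    eFC_raw: float | None = None
    corrFC: float | None = None
    ssimFC: float | None = None


def bandpass_phase(
    ts: np.ndarray,
    TR: float,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = 2,
    edge_trim: int = 10,
) -> PhaseField:
    """Zero-phase Butterworth band-pass then Hilbert phase per node.

    ``edge_trim`` volumes are removed at each end to discard filter and
    analytic-signal edge effects.
    """
    from scipy.signal import butter, filtfilt, hilbert

    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    n, T = ts.shape
    fs = 1.0 / TR
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} outside (0, {fs / 2:.3g}) Hz")
    if T <= 3 * (2 * order + 1):
        raise ValueError("time series too short for the requested filter")
    b, a = butter(order, [lo, hi], btype="bandpass", fs=fs)
    filt = filtfilt(b, a, ts - ts.mean(axis=1, keepdims=True), axis=1)
    phases = np.angle(hilbert(filt, axis=1))
    if edge_trim:
        if 2 * edge_trim >= T:
            raise ValueError("edge_trim removes the whole series")
        phases = phases[:, edge_trim:-edge_trim]
        filt = filt[:, edge_trim:-edge_trim]
    return PhaseField(phases=phases, filtered=filt, band=band, edge_trim=edge_trim)


def _weight_matrix(weights) -> np.ndarray:
    """Resolve local-order-parameter weights.

    A raw array is used as-is. An EDR-kind CouplingMatrix gets its unit
    self-weight restored (exp(-lambda*0) = 1): the local order parameter
    includes the node's own phase.
    """
    if isinstance(weights, CouplingMatrix):
        w = weights.weights.copy()
        if weights.kind in {"EDR", "EDR_LR"}:
            np.fill_diagonal(w, 1.0)
        return w
    return np.asarray(weights, dtype=float)


def local_kuramoto(phases: PhaseField | np.ndarray, weights) -> np.ndarray:
    """Local Kuramoto order parameter moduli R_n(t) in [0, 1].

    R_n(t) is the modulus of the row-normalized weighted mean of the
    phase factors e^{i phi_p(t)}; the weight of node p on node n is
    C_np / sum_q C_nq.
    """
    ph = phases.phases if isinstance(phases, PhaseField) else np.asarray(phases)
    w = _weight_matrix(weights)
    rows = w.sum(axis=1)
    if np.any(rows <= 0):
        raise ValueError("local Kuramoto weights need strictly positive row sums")
    z = np.exp(1j * ph)
    R = np.abs((w @ z) / rows[:, None])
    return np.clip(R, 0.0, 1.0)


def amplitude_turbulence(R: np.ndarray) -> float:
    """Amplitude turbulence D: SD of R_n(t) pooled over nodes and time."""
    R = np.asarray(R, dtype=float)
    if R.size == 0:
        raise ValueError("empty local order parameter field")
    return float(np.sqrt(max(np.mean(R**2) - np.mean(R) ** 2, 0.0)))


def global_kuramoto(phases: PhaseField | np.ndarray) -> np.ndarray:
    """Global Kuramoto order parameter gR(t) = |mean_p e^{i phi_p(t)}|."""
    ph = phases.phases if isinstance(phases, PhaseField) else np.asarray(phases)
    return np.abs(np.exp(1j * ph).mean(axis=0))


def metastability(gR: np.ndarray) -> float:
    """Metastability M: standard deviation of gR(t) over time."""
    gR = np.asarray(gR, dtype=float)
    return float(np.sqrt(max(np.mean(gR**2) - np.mean(gR) ** 2, 0.0)))


def functional_connectivity(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation between all pairs of node signals."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    fc = np.corrcoef(ts)
    return np.atleast_2d(fc)


def _global_ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Single global structural-similarity index on [0,1]-rescaled matrices.

    Conventional stabilizing constants C1 = (0.01)^2, C2 = (0.03)^2 for
    unit data range; no windowing.
    """
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    span = hi - lo if hi > lo else 1.0
    a = (a - lo) / span
    b = (b - lo) / span
    c1, c2 = 0.01**2, 0.03**2
    mu_a, mu_b = a.mean(), b.mean()
    va, vb = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(
        ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
        / ((mu_a**2 + mu_b**2 + c1) * (va + vb + c2))
    )


def fc_metrics(fc_sim: np.ndarray, fc_emp: np.ndarray) -> FitErrors:
    """FC comparison metrics between simulated and empirical matrices.

    eFC is the root-mean-square difference of the upper-triangle vectors
    (the raw Euclidean norm is also reported); corrFC the Pearson
    correlation over upper triangles; ssimFC a single global structural
    similarity index.
    """
    fc_sim = np.asarray(fc_sim, dtype=float)
    fc_emp = np.asarray(fc_emp, dtype=float)
    if fc_sim.shape != fc_emp.shape:
        raise ValueError("FC matrices must have the same shape")
    iu = np.triu_indices(fc_sim.shape[0], k=1)
    u, v = fc_sim[iu], fc_emp[iu]
    raw = float(np.linalg.norm(u - v))
    eFC = raw / np.sqrt(u.size)
    if np.std(u) == 0 or np.std(v) == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(u, v)[0, 1])
    return FitErrors(
        eFC=eFC,
        eFC_raw=raw,
        corrFC=corr,
        ssimFC=_global_ssim(fc_sim, fc_emp),
    )


def turbulence_error(D_sim: float, D_emp: float) -> float:
    """eD = |D_sim - D_emp|."""
    return abs(float(D_sim) - float(D_emp))


def metastability_error(M_sim: float, M_emp: float) -> float:
    """eM = |M_sim - M_emp|."""
    return abs(float(M_sim) - float(M_emp))
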