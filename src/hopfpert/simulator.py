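"""Coupled stochastic Stuart-Landau (Hopf) network integrator.

Each region follows the normal form of a supercritical Hopf bifurcation
with shear,

    dz/dt = (a + i*omega) z - (1 + i*beta) z |z|^2 + coupling + forcing + noise,

written in Cartesian coordinates (z = x + iy) and coupled diffusively
through a structural matrix C scaled by a global factor G:

    dx_i/dt = a_i x_i + (x_i^2+y_i^2)(beta y_i - x_i) - omega_i y_i
              + G * sum_j C_ij (x_j - x_i) + F0_i cos(omega_f t) + nu eta_i(t)
    dy_i/dt = a_i y_i - (x_i^2+y_i^2)(beta x_i + y_i) + omega_i x_i
              + G * sum_j C_ij (y_j - y_i) + F0_i sin(omega_f t) + nu eta'_i(t)

The bifurcation parameter ``a`` selects the regime: a << 0 noise, a just
below 0 subcritical fluctuations, a > 0 supercritical oscillations. The
shear (nonisochronicity) ``beta`` couples amplitude to frequency: on the
limit cycle r = sqrt(a) the rotation rate is omega - beta*a.

Integration uses integer substepping so the output sampling interval TR
is an exact multiple of dt; x = Re(z) is the simulated BOLD signal. The
default scheme is stochastic Heun (trapezoidal drift with the noise
increment entering the predictor), which for additive noise removes the
O(dt) bias that plain Euler-Maruyama leaves in the stationary
fluctuation amplitude; Euler-Maruyama remains available via
``scheme="euler"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "ForcingSpec",
    "SimulationResult",
    "DivergenceError",
    "simulate",
    "estimate_node_frequencies",
]


class DivergenceError(RuntimeError):
    """Numerical blow-up of the trajectory (step and node reported)."""


def _drift(x, y, t, a, omega, beta, G, C, row, f0, wf):
    """Deterministic right-hand side of the coupled system."""
    r2 = x * x + y * y
    dx = a * x + r2 * (beta * y - x) - omega * y + G * (C @ x - row * x)
    dy = a * y - r2 * (beta * x + y) + omega * x + G * (C @ y - row * y)
    if f0 is not None:
        dx = dx + f0 * np.cos(wf * t)
        dy = dy + f0 * np.sin(wf * t)
    return dx, dy


@dataclass
class ModelParams:
    """Parameters of one simulation regime.

    Parameters
    ----------
    a : float or (N,) array
        Bifurcation parameter (scalar broadcast to all nodes).
    omega : (N,) array
        Intrinsic angular frequencies, rad/s; must be positive.
    beta : float
        Shear (nonisochronicity) factor.
    G : float
        Global coupling scale.
    nu : float
        Additive Gaussian noise standard deviation (default 0.01, the
        value used across the Hopf whole-brain literature).
    dt : float
        Requested integrator step in s; internally adjusted so that
        TR/dt is an integer (default 0.1 -> TR/7 for TR = 0.72 s).
    TR : float
        Output sampling interval in s (0.72, the HCP repetition time).
    n_volumes : int
        Retained output length in volumes.
    discard : int
        Transient volumes dropped before recording.
    """

    a: float | np.ndarray
    omega: np.ndarray
    beta: float = 0.0
    G: float = 0.0
    nu: float = 0.01
    dt: float = 0.1
    TR: float = 0.72
    n_volumes: int = 400
    discard: int = 20
    independent_xy_noise: bool = True
    scheme: str = "heun"

    def __post_init__(self) -> None:
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if not np.all(np.isfinite(self.omega)) or np.any(self.omega <= 0):
            raise ValueError("omega must be finite and positive")
        self.a = np.broadcast_to(
            np.asarray(self.a, dtype=float), self.omega.shape
        ).copy()
        if self.dt <= 0 or self.TR <= 0:
            raise ValueError("dt and TR must be positive")
        if self.nu < 0:
            raise ValueError("nu must be nonnegative")
        if self.n_volumes < 1 or self.discard < 0:
            raise ValueError("n_volumes >= 1 and discard >= 0 required")
        if self.scheme not in {"heun", "euler"}:
            raise ValueError(f"unknown integration scheme {self.scheme!r}")

    @property
    def n_nodes(self) -> int:
        return self.omega.size

    @property
    def dt_stable(self) -> float:
        """Euler stability bound for the supercritical limit cycle.

        Linearizing around the limit cycle r = sqrt(a) gives step
        eigenvalues of magnitude ~ a*(1+beta^2); the forward-Euler
        radius requires dt < 1/(a*(1+beta^2)), and a safety factor of 5
        is applied. Subcritical dynamics (a <= 0) impose no bound.
        """
        amax = float(np.max(self.a))
        if amax <= 0:
            return np.inf
        return 1.0 / (amax * (1.0 + self.beta**2)) / 5.0

    @property
    def substeps(self) -> int:
        """Integrator substeps per volume (dt adjusted to TR/substeps).

        The requested dt is reduced automatically when the supercritical
        stability bound requires it.
        """
        n = max(1, round(self.TR / self.dt))
        bound = self.dt_stable
        if self.TR / n > bound:
            n = int(np.ceil(self.TR / bound))
        return n

    @property
    def dt_effective(self) -> float:
        return self.TR / self.substeps

    def replace(self, **kw) -> "ModelParams":
        from dataclasses import asdict

        d = asdict(self)
        d.update(kw)
        return ModelParams(**d)


@dataclass
class ForcingSpec:
    """Additive periodic forcing F_j = F0_j [cos(w_j t) + i sin(w_j t)].

    ``schedule`` is "off", "sustained", or ("on_then_off", n_on, n_off):
    forcing active for the first n_on retained volumes then switched off
    for the remaining n_off. During the discarded transient the forcing
    state matches the first retained volume.
    """

    F0: np.ndarray | float = 0.0
    omega_forcing: np.ndarray | None = None
    schedule: object = "off"

    def resolve(self, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
        n = params.n_nodes
        f0 = np.broadcast_to(np.asarray(self.F0, dtype=float), (n,)).copy()
        if np.any(f0 < 0):
            raise ValueError("forcing amplitudes must be nonnegative")
        if self.omega_forcing is None:
            wf = params.omega.copy()
        else:
            wf = np.broadcast_to(
                np.asarray(self.omega_forcing, dtype=float), (n,)
            ).copy()
        return f0, wf

    def on_flags(self, n_volumes: int) -> np.ndarray:
        """Boolean per-retained-volume forcing state."""
        if self.schedule == "off":
            return np.zeros(n_volumes, dtype=bool)
        if self.schedule == "sustained":
            return np.ones(n_volumes, dtype=bool)
        try:
            tag, n_on, n_off = self.schedule
        except (TypeError, ValueError):
            raise ValueError(f"unknown forcing schedule {self.schedule!r}")
        if tag != "on_then_off":
            raise ValueError(f"unknown forcing schedule {self.schedule!r}")
        if n_on + n_off != n_volumes:
            raise ValueError(
                f"schedule covers {n_on + n_off} volumes but the run has {n_volumes}"
            )
        flags = np.zeros(n_volumes, dtype=bool)
        flags[:n_on] = True
        return flags


@dataclass
class SimulationResult:
    """Simulated trajectory sampled at TR after transient discard."""

    x: np.ndarray
    y: np.ndarray
    TR: float
    seed: object
    forcing_on: np.ndarray = field(default=None, repr=False)

    @property
    def bold(self) -> np.ndarray:
        """The simulated BOLD signal, Re(z)."""
        return self.x


def simulate(
    params: ModelParams,
    coupling,
    forcing: ForcingSpec | None = None,
    seed: object = 0,
) -> SimulationResult:
    """Integrate the coupled system by Euler-Maruyama and sample at TR.

    The same (params, coupling, forcing, seed) always yields a
    bit-identical trajectory; the number and order of noise draws does
    not depend on the forcing, so perturbed/unperturbed runs sharing a
    seed see identical noise (paired design).
    """
    if forcing is None:
        forcing = ForcingSpec()
    C = coupling.weights if hasattr(coupling, "weights") else np.asarray(coupling, float)
    n = params.n_nodes
    if C.shape != (n, n):
        raise ValueError(f"coupling is {C.shape}, params define {n} nodes")
    f0, wf = forcing.resolve(params)
    flags = forcing.on_flags(params.n_volumes)
    transient_on = bool(flags[0]) if flags.size else False

    dt = params.dt_effective
    sub = params.substeps
    sqdt = np.sqrt(dt)
    a, omega, beta, G, nu = params.a, params.omega, params.beta, params.G, params.nu
    row = C.sum(axis=1)
    guard = 10.0 * max(1.0, np.sqrt(max(float(np.max(a)), 0.0)))

    heun = params.scheme == "heun"
    rng = np.random.default_rng(seed)
    x = rng.uniform(-0.1, 0.1, size=n)
    y = rng.uniform(-0.1, 0.1, size=n)

    total = params.discard + params.n_volumes
    out_x = np.empty((n, params.n_volumes))
    out_y = np.empty((n, params.n_volumes))
    any_forcing = np.any(f0 > 0)

    t = 0.0
    for vol in range(total):
        retained = vol - params.discard
        force_on = any_forcing and (
            flags[retained] if retained >= 0 else transient_on
        )
        for _ in range(sub):
            if nu > 0:
                if params.independent_xy_noise:
                    eta = rng.standard_normal((2, n))
                    wx, wy = nu * sqdt * eta[0], nu * sqdt * eta[1]
                else:
                    eta = nu * sqdt * rng.standard_normal(n)
                    wx = wy = eta
            else:
                wx = wy = 0.0
            dx, dy = _drift(x, y, t, a, omega, beta, G, C, row,
                            f0 if force_on else None, wf)
            if heun:
                # noise enters the predictor: trapezoidal drift acting on
                # the increment removes the O(dt) stationary-variance bias
                xp = x + dt * dx + wx
                yp = y + dt * dy + wy
                dx2, dy2 = _drift(xp, yp, t + dt, a, omega, beta, G, C, row,
                                  f0 if force_on else None, wf)
                x = x + 0.5 * dt * (dx + dx2) + wx
                y = y + 0.5 * dt * (dy + dy2) + wy
            else:
                x = x + dt * dx + wx
                y = y + dt * dy + wy
            t += dt
        r2 = x * x + y * y
        if np.any(r2 > guard * guard) or not np.all(np.isfinite(r2)):
            finite = np.isfinite(r2)
            bad = int(np.argmax(~finite)) if not finite.all() else int(np.argmax(r2))
            raise DivergenceError(
                f"|z| exceeded guard {guard:.3g} at volume {vol}, node {bad}"
            )
        if retained >= 0:
            out_x[:, retained] = x
            out_y[:, retained] = y

    return SimulationResult(x=out_x, y=out_y, TR=params.TR, seed=seed, forcing_on=flags)


def estimate_node_frequencies(
    bold: np.ndarray,
    TR: float,
    band: tuple[float, float] = (0.008, 0.08),
    flatness_ratio: float = 4.0,
) -> np.ndarray:
    """Per-node intrinsic angular frequencies from the band-limited spectrum.

    Welch power spectra are computed per node and omega_n = 2*pi*f_peak
    with f_peak the in-band argmax. A node whose in-band peak does not
    exceed ``flatness_ratio`` times the in-band median power is treated
    as spectrally flat: a warning is emitted and the band midpoint is
    used instead.
    """
    from scipy.signal import welch

    bold = np.atleast_2d(np.asarray(bold, dtype=float))
    n, T = bold.shape
    fs = 1.0 / TR
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError("band must lie within (0, Nyquist)")
    nperseg = min(T, max(256, T // 3))
    freqs, pxx = welch(bold, fs=fs, nperseg=nperseg, detrend="constant", axis=-1)
    in_band = (freqs >= lo) & (freqs <= hi)
    if in_band.sum() < 3:
        raise ValueError("too few spectral bins in band; longer series needed")
    fb, pb = freqs[in_band], pxx[:, in_band]
    omega = np.empty(n)
    fallback = 2 * np.pi * 0.5 * (lo + hi)
    flat = []
    for i in range(n):
        med = np.median(pb[i])
        peak = pb[i].max()
        if med <= 0 or peak < flatness_ratio * med:
            flat.append(i)
            omega[i] = fallback
        else:
            omega[i] = 2 * np.pi * fb[int(np.argmax(pb[i]))]
    if flat:
        warnings.warn(
            f"flat in-band spectrum for node(s) {flat}; using band midpoint",
            RuntimeWarning,
            stacklevel=2,
        )
    return omega
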