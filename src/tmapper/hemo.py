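"""Balloon-Windkessel hemodynamic forward model.

Neural activity S_E drives, per region, a vasodilatory signal s, blood
inflow f, blood volume v and deoxyhemoglobin content q:

    ds/dt = S_E - kappa*s - gamma_h*(f - 1)
    df/dt = s
    tau_h * dv/dt = f - v**(1/alpha)
    tau_h * dq/dt = f*(1 - (1 - rho)**(1/f))/rho - v**(1/alpha - 1)*q

    BOLD = V0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v))

The resting state (s, f, v, q) = (0, 1, 1, 1) is the hemodynamic
equilibrium without neural activity; the BOLD signal vanishes there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .model import NeuralTrajectory
from .timeseries import MultivariateTimeSeries

__all__ = [
    "HemodynamicParameters",
    "BoldSeries",
    "simulate_bold",
    "hemodynamic_drift",
    "find_hemodynamic_equilibrium",
    "downsample",
]


@dataclass(frozen=True)
class HemodynamicParameters:
    """Balloon-Windkessel parameters (standard 1.5T calibration).

    k1 and k3 default to the rho-derived values 7*rho and 2*rho - 0.2;
    pass explicit values to override.
    """

    kappa: float = 0.65    # rate of signal decay (1/s)
    gamma_h: float = 0.41  # rate of flow-dependent elimination (1/s)
    tau_h: float = 0.98    # hemodynamic transit time (s)
    alpha: float = 0.32    # Grubb's exponent
    rho: float = 0.34      # resting oxygen extraction fraction
    V0: float = 0.02       # resting blood volume fraction
    k1: float | None = None
    k2: float = 2.0
    k3: float | None = None

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma_h", "tau_h", "alpha", "rho", "V0", "k2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.k1 is None:
            object.__setattr__(self, "k1", 7.0 * self.rho)
        if self.k3 is None:
            object.__setattr__(self, "k3", 2.0 * self.rho - 0.2)


@dataclass
class BoldSeries:
    """BOLD signal change (dimensionless), T x N, with time stamps."""

    times: np.ndarray
    bold: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.bold.shape[1]


def hemodynamic_drift(state: np.ndarray, drive: np.ndarray, hp: HemodynamicParameters) -> np.ndarray:
    """Right-hand side of the Balloon-Windkessel ODEs.

    ``state`` is (4, N): rows are s, f, v, q; ``drive`` is the length-N
    neural input S_E.
    """
    s, f, v, q = state
    ds = drive - hp.kappa * s - hp.gamma_h * (f - 1.0)
    df = s
    dv = (f - v ** (1.0 / hp.alpha)) / hp.tau_h
    dq = (
        f * (1.0 - (1.0 - hp.rho) ** (1.0 / f)) / hp.rho
        - v ** (1.0 / hp.alpha - 1.0) * q
    ) / hp.tau_h
    return np.stack((ds, df, dv, dq))


def _bold_signal(v: np.ndarray, q: np.ndarray, hp: HemodynamicParameters) -> np.ndarray:
    return hp.V0 * (hp.k1 * (1.0 - q) + hp.k2 * (1.0 - q / v) + hp.k3 * (1.0 - v))


def simulate_bold(
    traj: NeuralTrajectory,
    hparams: HemodynamicParameters | None = None,
    dt: float | None = None,
) -> BoldSeries:
    """Forward-Euler integration of the Balloon-Windkessel model driven by S_E.

    The initial condition is the equilibrium (s, f, v, q) = (0, 1, 1, 1).
    Raises if blood inflow or volume become nonpositive (the model is only
    defined for f, v > 0).
    """
    hp = hparams if hparams is not None else HemodynamicParameters()
    if dt is None:
        dt = traj.dt
    steps = np.diff(traj.times)
    if steps.size and not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("trajectory must be uniformly sampled at dt")
    T, N = traj.S_E.shape
    state = np.zeros((4, N))
    state[1:] = 1.0  # f = v = q = 1
    bold = np.empty((T, N))
    bold[0] = _bold_signal(state[2], state[3], hp)
    for n in range(1, T):
        state = state + dt * hemodynamic_drift(state, traj.S_E[n - 1], hp)
        bad = (state[1] <= 0) | (state[2] <= 0)
        if np.any(bad):
            region = int(np.flatnonzero(bad)[0])
            raise FloatingPointError(
                f"blood inflow/volume became nonpositive in region {region} at step {n}"
            )
        bold[n] = _bold_signal(state[2], state[3], hp)
    return BoldSeries(times=traj.times.copy(), bold=bold)


def find_hemodynamic_equilibrium(
    x0=(0.1, 1.2, 0.9, 1.1),
    drive: float = 0.0,
    hparams: HemodynamicParameters | None = None,
    tol: float = 1e-12,
) -> np.ndarray:
    """Solve the stationarity conditions of the Balloon-Windkessel ODEs.

    Root-finding on the drift for a single region under constant neural
    drive.  With ``drive = 0`` this recovers the resting equilibrium
    (0, 1, 1, 1) from any reasonable starting point.
    """
    hp = hparams if hparams is not None else HemodynamicParameters()

    def f(y):
        return hemodynamic_drift(y.reshape(4, 1), np.array([drive]), hp).ravel()

    sol = optimize.root(f, np.asarray(x0, dtype=float), tol=tol)
    if not sol.success:
        raise RuntimeError(f"equilibrium search failed: {sol.message}")
    return sol.x


def downsample(series, TR: float = 0.72, t_start: float = 0.0) -> MultivariateTimeSeries:
    """Nearest-sample decimation at times t_start + m*TR.

    Accepts a BoldSeries, NeuralTrajectory or MultivariateTimeSeries and
    returns a MultivariateTimeSeries; channel order is preserved.  No
    anti-alias filtering is applied (pure decimation).
    """
    if isinstance(series, BoldSeries):
        times, X = series.times, series.bold
    elif isinstance(series, NeuralTrajectory):
        times, X = series.times, series.S_E
    elif isinstance(series, MultivariateTimeSeries):
        times, X = series.times, series.X
    else:
        raise TypeError("unsupported series type")
    dt = times[1] - times[0] if len(times) > 1 else TR
    if TR < dt - 1e-12:
        raise ValueError(f"TR ({TR}) must be at least the native sampling step ({dt})")
    t_end = times[-1]
    m = np.arange(int(np.floor((t_end - t_start) / TR + 1e-9)) + 1)
    targets = t_start + m * TR
    idx = np.clip(np.round((targets - times[0]) / dt).astype(int), 0, len(times) - 1)
    return MultivariateTimeSeries(X=X[idx], times=times[idx])
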