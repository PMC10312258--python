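"""Multistable neural-mass network model and stochastic Heun integration.

Each brain region holds an excitatory (E) and an inhibitory (I) population
described by synaptic gating variables S_E, S_I (fraction of open channels).
Regions interact through a nonnegative, zero-diagonal long-range coupling
matrix C scaled by a global coupling parameter G, which may vary slowly in
time and acts as the control parameter deforming the dynamic landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "Connectome",
    "ControlProtocol",
    "NeuralTrajectory",
    "transfer_rate",
    "normalize_connectome",
    "drift_field",
    "integrate_sde",
    "make_protocol",
]

# Admissible range for the global coupling parameter G (nA).
G_RANGE = (1.1, 5.0)


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the two-population neural-mass model.

    Defaults are the standard values inherited from the reduced Wong-Wang
    lineage of whole-brain models (decay times in seconds, transfer-function
    parameters in nC^-1 / Hz / s, synaptic weights in nA).
    """

    tau_E: float = 0.1     # decay time of NMDA conductance (s)
    tau_I: float = 0.01    # decay time of GABA conductance (s)
    gamma_E: float = 0.641
    gamma_I: float = 1.0
    a_E: float = 310.0     # nC^-1
    b_E: float = 125.0     # Hz
    d_E: float = 0.16      # s
    a_I: float = 615.0     # nC^-1
    b_I: float = 177.0     # Hz
    d_I: float = 0.087     # s
    r_max: float = 500.0   # maximal firing rate (Hz)
    w_EE: float = 2.8      # nA
    w_EI: float = 1.0      # nA
    w_IE: float = 2.8      # nA
    w_II: float = 0.05     # nA
    I_I: float = 0.1       # background input to I population (nA)
    sigma: float = 0.01    # noise amplitude

    def __post_init__(self) -> None:
        for name in (
            "tau_E", "tau_I", "gamma_E", "gamma_I", "a_E", "b_E", "d_E",
            "a_I", "b_I", "d_I", "r_max", "w_EE", "w_EI", "w_IE", "w_II", "I_I",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def pop(self, which: str) -> tuple[float, float, float]:
        """(a, b, d) for population 'E' or 'I'."""
        if which == "E":
            return self.a_E, self.b_E, self.d_E
        if which == "I":
            return self.a_I, self.b_I, self.d_I
        raise ValueError("population must be 'E' or 'I'")

    def with_(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass
class Connectome:
    """Nonnegative long-range coupling matrix, infinity-norm normalized.

    Invariants: C_ij >= 0, C_ii = 0, and max_i sum_j |C_ij| = 1.
    """

    C: np.ndarray
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("connectome matrix must be square")
        if np.any(self.C < 0):
            raise ValueError("connectome entries must be nonnegative")
        if np.any(np.diag(self.C) != 0):
            raise ValueError("connectome diagonal must be zero")
        rs = np.abs(self.C).sum(axis=1).max()
        if abs(rs - 1.0) > 1e-9:
            raise ValueError(
                "connectome must be normalized to unit maximum row sum "
                f"(got {rs}); use normalize_connectome"
            )

    @property
    def n_regions(self) -> int:
        return self.C.shape[0]


def normalize_connectome(C_raw: np.ndarray, region_names: list[str] | None = None) -> Connectome:
    """Zero the diagonal and rescale so the maximum absolute row sum is 1.

    The normalization makes the effect of the global coupling G comparable
    across connectomes.  Idempotent and scale invariant.
    """
    C = np.array(C_raw, dtype=float, copy=True)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("connectome matrix must be square")
    if np.any(~np.isfinite(C)):
        raise ValueError("connectome contains non-finite entries")
    if np.any(C < 0):
        raise ValueError("connectome entries must be nonnegative")
    np.fill_diagonal(C, 0.0)
    norm = np.abs(C).sum(axis=1).max()
    if norm == 0:
        raise ValueError("degenerate connectome: all off-diagonal entries are zero")
    return Connectome(C / norm, region_names=region_names)


@dataclass(frozen=True)
class ControlProtocol:
    """Piecewise-linear time course of the global coupling G(t).

    Constant extrapolation is used beyond the first/last breakpoint.
    """

    times: np.ndarray
    values: np.ndarray

    def __call__(self, t) -> np.ndarray | float:
        return np.interp(t, self.times, self.values)


def make_protocol(breakpoints: list[tuple[float, float]], g_range: tuple[float, float] = G_RANGE) -> ControlProtocol:
    """Build a G(t) protocol from (time, G) breakpoints.

    Times must be strictly increasing; G values outside ``g_range`` trigger
    a warning (the model is only calibrated inside the admissible range).
    """
    pts = np.asarray(breakpoints, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, 2)
    if pts.shape[0] < 1 or pts.shape[1] != 2:
        raise ValueError("protocol needs at least one (time, G) breakpoint")
    t, g = pts[:, 0], pts[:, 1]
    if np.any(np.diff(t) <= 0):
        raise ValueError("breakpoint times must be strictly increasing")
    if np.any(g < g_range[0]) or np.any(g > g_range[1]):
        warnings.warn(
            f"protocol G values outside the admissible range {g_range}",
            stacklevel=2,
        )
    return ControlProtocol(times=t, values=g)


@dataclass
class NeuralTrajectory:
    """Simulated gating-variable trajectory.

    S_E, S_I are T x N; G_trace holds G(t) at the recorded times.
    """

    times: np.ndarray
    S_E: np.ndarray
    S_I: np.ndarray
    G_trace: np.ndarray
    seed: int | None = None
    dt: float = field(default=0.001)

    @property
    def n_regions(self) -> int:
        return self.S_E.shape[1]


def decimate_trajectory(traj: NeuralTrajectory, TR: float, t_start: float = 0.0) -> NeuralTrajectory:
    """Nearest-sample decimation of a trajectory (state and G trace) at TR."""
    dt = traj.times[1] - traj.times[0] if len(traj.times) > 1 else TR
    if TR < dt - 1e-12:
        raise ValueError(f"TR ({TR}) must be at least the native step ({dt})")
    m = np.arange(int(np.floor((traj.times[-1] - t_start) / TR + 1e-9)) + 1)
    idx = np.clip(
        np.round((t_start + m * TR - traj.times[0]) / dt).astype(int),
        0,
        len(traj.times) - 1,
    )
    return NeuralTrajectory(
        times=traj.times[idx],
        S_E=traj.S_E[idx],
        S_I=traj.S_I[idx],
        G_trace=traj.G_trace[idx],
        seed=traj.seed,
        dt=TR,
    )


def transfer_rate(x, pop: str, params: ModelParameters | None = None):
    """Population transfer function H_p: synaptic current (nA) -> firing rate (Hz).

    A sigmoidal conversion of the soft-rectifier transfer function that keeps
    the rectifier's a_p, b_p, d_p parameters while saturating at r_max:

        u = a_p x - b_p
        H(x) = [ r_max + (u - r_max) / (1 - exp(d_p (u - r_max))) ]
               / (1 - exp(-d_p u))

    For u << r_max this reduces to the classic soft rectifier
    u / (1 - exp(-d_p u)); for large u it saturates at r_max.  Monotone
    nondecreasing and bounded in [0, r_max].
    """
    if params is None:
        params = ModelParameters()
    a, b, d = params.pop(pop)
    r = params.r_max
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("transfer_rate input must be finite")
    u = a * x - b
    w = u - r
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        zw = np.clip(d * w, -700.0, 700.0)
        inner = np.where(np.abs(w) < 1e-10, r - 1.0 / d, r + w / (-np.expm1(zw)))
        zu = np.clip(-d * u, -700.0, 700.0)
        denom = -np.expm1(zu)
        out = np.where(np.abs(u) < 1e-10, 1.0 / d, inner / denom)
    return out if out.ndim else float(out)


def drift_field(
    S_E: np.ndarray,
    S_I: np.ndarray,
    G: float,
    conn: Connectome,
    params: ModelParameters | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic drift (dS_E/dt, dS_I/dt) of the global model.

    The long-range input to region i is I_G^(i) = G * sum_{j != i} C_ij S_E^(j)
    (the j != i restriction is enforced by the zero diagonal of C).
    """
    if params is None:
        params = ModelParameters()
    S_E = np.asarray(S_E, dtype=float).ravel()
    S_I = np.asarray(S_I, dtype=float).ravel()
    N = conn.n_regions
    if S_E.shape[0] != N or S_I.shape[0] != N:
        raise ValueError(
            f"state vectors must have length {N} (got {S_E.shape[0]}, {S_I.shape[0]})"
        )
    I_G = G * (conn.C @ S_E)
    x_E = params.w_EE * S_E - params.w_IE * S_I + I_G
    x_I = params.w_EI * S_E - params.w_II * S_I + params.I_I
    dSE = -S_E / params.tau_E + (1.0 - S_E) * params.gamma_E * transfer_rate(x_E, "E", params)
    dSI = -S_I / params.tau_I + (1.0 - S_I) * params.gamma_I * transfer_rate(x_I, "I", params)
    return dSE, dSI


def _drift_flat(y: np.ndarray, G: float, conn: Connectome, params: ModelParameters) -> np.ndarray:
    N = conn.n_regions
    dE, dI = drift_field(y[:N], y[N:], G, conn, params)
    return np.concatenate((dE, dI))


def integrate_sde(
    x0: tuple[np.ndarray, np.ndarray] | np.ndarray,
    protocol: ControlProtocol,
    conn: Connectome,
    params: ModelParameters | None = None,
    duration: float = 60.0,
    dt: float = 0.001,
    seed: int | None = None,
    record_every: int = 1,
    clip_state: bool = False,
) -> NeuralTrajectory:
    """Stochastic Heun (predictor-corrector) integration of the global model.

    Additive noise: each state variable receives independent standard
    Gaussian increments scaled by sigma * sqrt(dt); the same increment is
    used in the predictor and the corrector step.  With sigma = 0 the scheme
    reduces to the deterministic Heun method, so trajectories are
    seed independent.

    Parameters
    ----------
    x0 : (S_E0, S_I0) pair of length-N vectors, or a flat 2N vector.
    record_every : keep every m-th step (the first and last are always kept
        on the recorded grid t = 0, m*dt, 2m*dt, ...).
    clip_state : clip gating variables into [0, 1] after every step.  Off by
        default: small noise-driven excursions outside [0, 1] are left intact.
    """
    if params is None:
        params = ModelParameters()
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least dt")
    N = conn.n_regions
    if isinstance(x0, tuple):
        y = np.concatenate([np.asarray(v, dtype=float).ravel() for v in x0])
    else:
        y = np.asarray(x0, dtype=float).ravel()
    if y.shape[0] != 2 * N:
        raise ValueError(f"initial state must have 2N = {2 * N} entries")

    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    sig = params.sigma * np.sqrt(dt)

    n_rec = n_steps // record_every + 1
    times = np.empty(n_rec)
    S_E = np.empty((n_rec, N))
    S_I = np.empty((n_rec, N))
    times[0] = 0.0
    S_E[0], S_I[0] = y[:N], y[N:]
    r = 1
    t = 0.0
    for step in range(n_steps):
        f0 = _drift_flat(y, float(protocol(t)), conn, params)
        if sig > 0:
            noise = sig * rng.standard_normal(2 * N)
        else:
            noise = 0.0
        y_pred = y + dt * f0 + noise
        f1 = _drift_flat(y_pred, float(protocol(t + dt)), conn, params)
        y = y + 0.5 * dt * (f0 + f1) + noise
        if clip_state:
            np.clip(y, 0.0, 1.0, out=y)
        t = (step + 1) * dt
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(
                f"state became non-finite at integration step {step + 1} (t = {t:.6g} s)"
            )
        if (step + 1) % record_every == 0:
            times[r] = t
            S_E[r], S_I[r] = y[:N], y[N:]
            r += 1
    times = times[:r]
    return NeuralTrajectory(
        times=times,
        S_E=S_E[:r],
        S_I=S_I[:r],
        G_trace=np.asarray(protocol(times), dtype=float),
        seed=seed,
        dt=dt * record_every,
    )
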