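"""Synthetic fixtures: a toy hysteresis system and a surrogate connectome.

The toy system is the scalar double-well normal form

    dx/dt = x - x^3 + g(t),

driven by a slow triangle-wave forcing g(t).  For |g| < g_c = 2/(3*sqrt(3))
the system is bistable with two attractor branches x_-(g) < 0 < x_+(g);
at |g| = g_c an attractor collides with the repeller (saddle-node) and the
state jumps to the surviving branch.  A triangle wave with amplitude
g_max > g_c therefore produces exactly two transitions per period, and the
ground-truth transition network, symbolic dynamics and attractor locations
are all known in closed form.  This is the desk-scale analog of a slowly
deforming neural dynamic landscape.

The synthetic connectome generator stands in for an empirical human
structural connectome: symmetric, nonnegative, zero-diagonal, with
log-normal weights and distance-decaying connection density on a ring, and
infinity-norm normalized.
"""

from __future__ import annotations

import warnings

import numpy as np

from .attractors import SymbolicSequence, build_truth_network
from .model import Connectome, normalize_connectome
from .network import TransitionNetwork
from .timeseries import MultivariateTimeSeries

__all__ = [
    "SADDLE_NODE_G",
    "triangle_wave",
    "toy_attractors",
    "toy_truth_symbols",
    "generate_toy_hysteresis",
    "generate_synthetic_connectome",
]

#: forcing amplitude at which an attractor of x - x^3 + g collides with the repeller
SADDLE_NODE_G = 2.0 / (3.0 * np.sqrt(3.0))


def triangle_wave(t, g_max: float, period: float) -> np.ndarray:
    """Triangle wave 0 -> +g_max -> 0 -> -g_max -> 0 over one period."""
    phase = np.mod(np.asarray(t, dtype=float) / period, 1.0)
    tri = np.where(phase < 0.5, 1.0 - 4.0 * np.abs(phase - 0.25),
                   -1.0 + 4.0 * np.abs(phase - 0.75))
    return g_max * tri


def toy_attractors(g: float) -> list[float]:
    """Stable roots of x - x^3 + g = 0, sorted ascending.

    A root x* is an attractor iff 1 - 3 x*^2 < 0.  Two attractors exist for
    |g| < g_c, one otherwise (and a marginal case exactly at |g| = g_c).
    """
    roots = np.roots([-1.0, 0.0, 1.0, g])
    real = roots[np.abs(roots.imag) < 1e-9].real
    stable = sorted(float(x) for x in real if 1.0 - 3.0 * x * x < 0)
    return stable


def toy_truth_symbols(g_values: np.ndarray, start_branch: int = 1) -> np.ndarray:
    """Closed-form symbolic dynamics of the hysteresis loop.

    Branch 1 is the lower attractor x_-(g) (exists for g < +g_c), branch 2
    the upper attractor x_+(g) (exists for g > -g_c).  The occupied branch
    persists until it is annihilated at the saddle-node, then switches —
    the deterministic hysteresis automaton.
    """
    g_values = np.asarray(g_values, dtype=float)
    sym = np.empty(g_values.size, dtype=int)
    branch = start_branch
    for i, g in enumerate(g_values):
        if branch == 2 and g < -SADDLE_NODE_G:
            branch = 1
        elif branch == 1 and g > SADDLE_NODE_G:
            branch = 2
        sym[i] = branch
    return sym


def generate_toy_hysteresis(
    g_max: float = 0.6,
    period: float = 125.0,
    n_periods: int = 4,
    dt: float = 0.005,
    noise: float = 0.2,
    seed: int | None = None,
    rate: float = 40.0,
    sample_dt: float = 0.25,
    embed_dim: int = 6,
    obs_noise: float = 0.1,
) -> tuple[MultivariateTimeSeries, TransitionNetwork, SymbolicSequence]:
    """Simulate the forced double-well system and its analytic ground truth.

    The state obeys dx/dt = rate * (x - x^3 + g(t)) with additive noise and
    a triangle-wave forcing; ``rate`` sets the separation of time scales
    between the fast relaxation within an attractor and the slow sweep of
    the control parameter (large rate means transitions complete within a
    sample or two, the regime the reconstruction method assumes).  The
    scalar state is embedded into ``embed_dim`` channels through a fixed
    random unit vector plus isotropic observation noise, emulating a noisy
    multichannel recording of a one-dimensional latent dynamic.

    Returns the sampled time series, the ground-truth two-node transition
    network derived from the closed-form attractor branches, and the
    analytic symbolic sequence.  The trajectory starts on the lower branch
    (x = -1) so each full triangle period produces exactly two transitions
    (up at g = +g_c, down at g = -g_c).

    With the defaults (g_max = 0.6 > g_c ~ 0.385, 4 periods of 125 s sampled
    every 0.25 s) the series has 2,001 samples and 8 transitions.
    """
    if g_max <= SADDLE_NODE_G:
        warnings.warn(
            f"g_max = {g_max} does not exceed the saddle-node threshold "
            f"{SADDLE_NODE_G:.4f}; no transitions will occur", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    duration = period * n_periods
    n_steps = int(round(duration / dt))
    every = max(1, int(round(sample_dt / dt)))

    x = -1.0  # start on the lower branch at g = 0
    sq = noise * np.sqrt(dt)
    rec_t = [0.0]
    rec_x = [x]
    for step in range(n_steps):
        t = step * dt
        g0 = float(triangle_wave(t, g_max, period))
        g1 = float(triangle_wave(t + dt, g_max, period))
        xi = sq * rng.standard_normal()
        f0 = rate * (x - x**3 + g0)
        xp = x + dt * f0 + xi
        x = x + 0.5 * dt * (f0 + rate * (xp - xp**3 + g1)) + xi
        if (step + 1) % every == 0:
            rec_t.append((step + 1) * dt)
            rec_x.append(x)
    times = np.array(rec_t)
    xs = np.array(rec_x)

    if embed_dim == 1:
        X = xs[:, None]
    else:
        w = rng.standard_normal(embed_dim)
        w /= np.linalg.norm(w)
        X = xs[:, None] * w[None, :]
    if obs_noise > 0:
        X = X + obs_noise * rng.standard_normal(X.shape)

    g_samples = triangle_wave(times, g_max, period)
    sym = SymbolicSequence(symbols=toy_truth_symbols(g_samples), times=times)
    truth = build_truth_network(sym)
    ts = MultivariateTimeSeries(X=X, times=times)
    return ts, truth, sym


def module_assignments(N: int, n_modules: int) -> np.ndarray:
    """Contiguous module labels for N regions split into n_modules groups."""
    sizes = [N // n_modules + (1 if i < N % n_modules else 0) for i in range(n_modules)]
    return np.repeat(np.arange(n_modules), sizes)


def generate_synthetic_connectome(
    N: int = 66,
    sparsity: float = 0.3,
    seed: int | None = None,
    n_modules: int | None = None,
    within: float = 1.0,
    between: float = 0.08,
) -> Connectome:
    """Random surrogate structural connectome.

    With ``n_modules=None`` (default) regions sit on a ring; connection
    probability decays with ring distance (scaled so the expected edge
    density is ``sparsity``), weights are log-normal, the matrix is
    symmetric with a zero diagonal, nearest ring neighbors are always
    connected (guaranteeing connectivity), and the result is normalized to
    unit maximum absolute row sum.

    With an integer ``n_modules`` the generator instead emulates the
    community structure of real structural connectomes: contiguous modules
    with strong log-normal within-module weights and weak between-module
    weights (``within``/``between`` scale factors).  Modular coupling gives
    each module its own activation threshold under global coupling, which
    is what produces a multi-branch attractor repertoire at small N.
    """
    if N < 2:
        raise ValueError("need at least two regions")
    rng = np.random.default_rng(seed)
    if n_modules is not None:
        mod = module_assignments(N, n_modules)
        W = rng.lognormal(0.0, 0.5, (N, N))
        W = np.where(mod[:, None] == mod[None, :], within * W, between * W)
        W = np.triu(W, 1)
        W = W + W.T
        return normalize_connectome(
            W, region_names=[f"M{m}R{i}" for i, m in enumerate(mod)]
        )
    ang = 2 * np.pi * np.arange(N) / N
    pos = np.column_stack([np.cos(ang), np.sin(ang)])
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    decay = np.exp(-d / (0.3 * d.max() + 1e-12))
    iu = np.triu_indices(N, 1)
    scale = sparsity / decay[iu].mean()
    prob = np.clip(scale * decay, 0.0, 1.0)
    keep = rng.random((N, N)) < prob
    W = np.where(keep, rng.lognormal(0.0, 1.0, size=(N, N)), 0.0)
    W = np.triu(W, 1)
    # always connect ring neighbors so the graph is connected
    ring = np.arange(N - 1)
    W[ring, ring + 1] = np.maximum(W[ring, ring + 1], rng.lognormal(0.0, 1.0, N - 1))
    W[0, N - 1] = max(W[0, N - 1], rng.lognormal(0.0, 1.0))
    W = W + W.T
    return normalize_connectome(W)


def demo_transition_pipeline(
    N: int = 10,
    n_modules: int = 3,
    connectome_seed: int = 0,
    sim_seed: int = 7,
    duration: float = 120.0,
    dt: float = 0.001,
    TR: float = 0.72,
    burn_in: float = 10.0,
    G_step: float = 0.05,
    k: int = 16,
    delta: int = 10,
) -> dict:
    """Scaled-down end-to-end demonstration of the full framework.

    Simulates a small modular network under a global-coupling protocol that
    repeatedly dips below the fold of the fully active attractor (two
    rise-and-fall arousal sweeps), derives BOLD, computes the attractor
    repertoire on a coarse G grid, assigns ground-truth symbols at the
    scanner TR, and reconstructs transition networks from both the
    down-sampled neural activity and the BOLD signal.

    Returns a dict with keys: connectome, protocol, trajectory, bold,
    repertoire, symbols, ts_neural, ts_bold, net_neural, net_bold,
    agreement_neural, agreement_bold.
    """
    from .analytics import symbolic_agreement
    from .attractors import assign_symbols, compute_repertoire
    from .hemo import downsample, simulate_bold
    from .mapper import run_temporal_mapper
    from .model import decimate_trajectory, integrate_sde, make_protocol  # noqa: F401

    conn = generate_synthetic_connectome(
        N=N, seed=connectome_seed, n_modules=n_modules
    )
    # two arousal sweeps dipping below the fold of the fully active state
    span = duration / 120.0
    proto = make_protocol(
        [
            (0.0, 5.0),
            (10.0 * span, 1.9),
            (35.0 * span, 1.15),
            (50.0 * span, 5.0),
            (60.0 * span, 1.9),
            (85.0 * span, 1.15),
            (100.0 * span, 5.0),
            (120.0 * span, 5.0),
        ]
    )
    x0 = np.concatenate([np.full(N, 0.95), np.full(N, 0.8)])
    traj = integrate_sde(
        x0, proto, conn, duration=duration, dt=dt, seed=sim_seed
    )
    bold = simulate_bold(traj)
    rep = compute_repertoire(
        conn,
        G_min=1.1,
        G_max=5.0,
        G_step=G_step,
        extra_starts=module_activation_starts(N, n_modules),
    )
    traj_tr = decimate_trajectory(traj, TR, t_start=burn_in)
    sym = assign_symbols(traj_tr, rep)
    ts_neural = downsample(traj, TR=TR, t_start=burn_in)
    ts_bold = downsample(bold, TR=TR, t_start=burn_in)
    net_neural = run_temporal_mapper(ts_neural, k=k, delta=delta)
    net_bold = run_temporal_mapper(ts_bold, k=k, delta=delta)
    return {
        "connectome": conn,
        "protocol": proto,
        "trajectory": traj,
        "bold": bold,
        "repertoire": rep,
        "symbols": sym,
        "ts_neural": ts_neural,
        "ts_bold": ts_bold,
        "net_neural": net_neural,
        "net_bold": net_bold,
        "agreement_neural": symbolic_agreement(net_neural, sym.symbols),
        "agreement_bold": symbolic_agreement(net_bold, sym.symbols),
    }


def module_activation_starts(N: int, n_modules: int) -> list[np.ndarray]:
    """Root-finding starts with every on/off combination of modules active.

    Active modules start at (S_E, S_I) = (0.95, 0.8), inactive at
    (0.02, 0.02); these seed the partial-activation fixed points that a
    homogeneous start lattice cannot reach.
    """
    import itertools

    mod = module_assignments(N, n_modules)
    starts = []
    for bits in itertools.product([0, 1], repeat=n_modules):
        on = np.array(bits)[mod] == 1
        se = np.where(on, 0.95, 0.02)
        si = np.where(on, 0.8, 0.02)
        starts.append(np.concatenate([se, si]))
    return starts
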