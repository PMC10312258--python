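"""Attractor repertoire and ground-truth transition network.

Fixed points of the deterministic neural-mass drift are located over a
grid of the control parameter G by multi-start root finding, classified by
the eigenvalues of the Jacobian, and clustered into attractor branches in
the product of state space and (scaled) parameter space.  Simulated time
points are then assigned to the nearest attractor (symbolic dynamics) and
the observed successions define the ground-truth transition network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .model import Connectome, ModelParameters, NeuralTrajectory, _drift_flat
from .network import TransitionNetwork

__all__ = [
    "FixedPoint",
    "AttractorRepertoire",
    "SymbolicSequence",
    "find_fixed_points",
    "classify_stability",
    "cluster_attractors",
    "assign_symbols",
    "build_truth_network",
    "compute_repertoire",
]

logger = logging.getLogger(__name__)

#: eigenvalue real parts must fall below -STABILITY_MARGIN to count as attracting
STABILITY_MARGIN = 1e-8


@dataclass
class FixedPoint:
    """A root of the deterministic drift at a given G."""

    state: np.ndarray          # 2N vector (S_E, S_I)
    G: float
    drift_norm: float
    eigenvalues: np.ndarray | None = None
    stability_class: str | None = None  # 'attractor' | 'non-attractor'

    @property
    def is_attractor(self) -> bool:
        return self.stability_class == "attractor"


@dataclass
class AttractorRepertoire:
    """Attractor branches in the product of state space and parameter space."""

    points: list[FixedPoint]
    branch_id: np.ndarray      # per-point branch label, contiguous from 1
    G_grid: np.ndarray
    scaling: float             # weight of the (normalized) G axis

    def __post_init__(self) -> None:
        self.branch_id = np.asarray(self.branch_id, dtype=int)
        if len(self.points) != len(self.branch_id):
            raise ValueError("branch_id must label every point")

    @property
    def n_branches(self) -> int:
        return int(self.branch_id.max()) if len(self.branch_id) else 0

    def _g_span(self) -> tuple[float, float]:
        g0, g1 = float(np.min(self.G_grid)), float(np.max(self.G_grid))
        return g0, max(g1 - g0, 1e-12)

    def features(self) -> np.ndarray:
        """Product-space coordinates (state, scaled G) of the repertoire."""
        g0, span = self._g_span()
        states = np.stack([fp.state for fp in self.points])
        g = np.array([(fp.G - g0) / span * self.scaling for fp in self.points])
        return np.column_stack([states, g])

    def embed(self, states: np.ndarray, G_values: np.ndarray) -> np.ndarray:
        """Embed samples into the same product space as features()."""
        g0, span = self._g_span()
        g = (np.asarray(G_values, dtype=float) - g0) / span * self.scaling
        return np.column_stack([np.atleast_2d(states), g])


@dataclass
class SymbolicSequence:
    """Per-time-point attractor branch labels."""

    symbols: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if self.symbols.shape != self.times.shape:
            raise ValueError("symbols and times must have the same length")


def _start_lattice(N: int, per_axis=(0.05, 0.5, 0.95)) -> list[np.ndarray]:
    """Homogeneous starting states: every region at the same (S_E, S_I)."""
    starts = []
    for se in per_axis:
        for si in per_axis:
            starts.append(np.concatenate([np.full(N, se), np.full(N, si)]))
    return starts


def find_fixed_points(
    conn: Connectome,
    params: ModelParameters | None = None,
    G_grid: np.ndarray | None = None,
    tol: float = 1e-9,
    dedup_tol: float = 1e-4,
    extra_starts: list[np.ndarray] | None = None,
) -> list[FixedPoint]:
    """Multi-start root finding on the deterministic drift over a G grid.

    For each G, roots are sought from a fixed lattice of homogeneous states
    plus continuation from the previous grid value's solutions.  Duplicate
    roots (within ``dedup_tol`` in the max norm) are merged; starts that fail
    to converge are logged and skipped.  Noise is irrelevant here: the drift
    is the sigma = 0 vector field.
    """
    if params is None:
        params = ModelParameters()
    if G_grid is None:
        G_grid = np.arange(1.1, 5.0 + 1e-9, 0.01)
    G_grid = np.atleast_1d(np.asarray(G_grid, dtype=float))
    N = conn.n_regions
    lattice = _start_lattice(N)
    if extra_starts:
        lattice = lattice + [np.asarray(s, dtype=float).ravel() for s in extra_starts]

    found: list[FixedPoint] = []
    prev_solutions: list[np.ndarray] = []
    for G in G_grid:
        roots_here: list[np.ndarray] = []
        for x0 in lattice + prev_solutions:
            sol = optimize.root(
                _drift_flat, x0, args=(float(G), conn, params), method="hybr",
                options={"xtol": 1e-13},
            )
            resid = np.max(np.abs(_drift_flat(sol.x, float(G), conn, params)))
            if resid >= tol:
                # one polishing pass from the candidate before giving up
                sol = optimize.root(
                    _drift_flat, sol.x, args=(float(G), conn, params),
                    method="hybr", options={"xtol": 1e-13},
                )
                resid = np.max(np.abs(_drift_flat(sol.x, float(G), conn, params)))
            if resid >= tol:
                logger.debug("root start rejected at G=%.3f (|drift|=%.2e)", G, resid)
                continue
            if any(np.max(np.abs(sol.x - r)) < dedup_tol for r in roots_here):
                continue
            roots_here.append(sol.x)
            found.append(FixedPoint(state=sol.x, G=float(G), drift_norm=float(resid)))
        prev_solutions = roots_here
    return found


def _fd_jacobian(fun, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian."""
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (fun(x + e) - fun(x - e)) / (2.0 * h)
    return J


def classify_stability(
    fp: FixedPoint,
    conn: Connectome,
    params: ModelParameters | None = None,
    margin: float = STABILITY_MARGIN,
) -> FixedPoint:
    """Attach the Jacobian spectrum and an attractor/non-attractor label.

    The Jacobian of the deterministic drift is computed by central finite
    differences; the point is an attractor iff every eigenvalue real part is
    below ``-margin`` (the margin guards against spurious neutral centers at
    numerical zero).
    """
    if params is None:
        params = ModelParameters()
    J = _fd_jacobian(lambda y: _drift_flat(y, fp.G, conn, params), fp.state)
    eig = np.linalg.eigvals(J)
    fp.eigenvalues = eig
    fp.stability_class = (
        "attractor" if np.max(eig.real) < -margin else "non-attractor"
    )
    return fp


def cluster_attractors(
    points: list[FixedPoint],
    G_grid: np.ndarray,
    link_threshold: float | None = None,
    G_scaling: float = 1.0,
) -> AttractorRepertoire:
    """Single-linkage clustering of attractors in state x (scaled G) space.

    Attractor points that map continuously onto each other as G varies chain
    together under single linkage and form one branch.  By default the G
    axis is rescaled to the unit interval (the numeric range of the gating
    variables) times ``G_scaling``, and the linkage cutoff is twice the
    median nearest-neighbor distance among the points.
    Branches are relabeled 1..B by increasing mean excitatory activation.
    """
    attractors = [fp for fp in points if fp.is_attractor]
    if not attractors:
        raise ValueError("no attractor points to cluster")
    rep = AttractorRepertoire(
        points=attractors,
        branch_id=np.ones(len(attractors), dtype=int),
        G_grid=np.atleast_1d(np.asarray(G_grid, dtype=float)),
        scaling=G_scaling,
    )
    X = rep.features()
    if len(attractors) == 1:
        return rep
    if link_threshold is None:
        D = cdist(X, X)
        np.fill_diagonal(D, np.inf)
        link_threshold = 2.0 * float(np.median(D.min(axis=1)))
    Z = linkage(X, method="single")
    raw = fcluster(Z, t=link_threshold, criterion="distance")
    # relabel branches by mean excitatory activation for determinism
    n_half = attractors[0].state.size // 2
    order = sorted(
        np.unique(raw),
        key=lambda b: float(
            np.mean([fp.state[:n_half].mean() for fp, r in zip(attractors, raw) if r == b])
        ),
    )
    remap = {b: i + 1 for i, b in enumerate(order)}
    rep.branch_id = np.array([remap[b] for b in raw], dtype=int)
    return rep


def assign_symbols(
    traj: NeuralTrajectory | tuple[np.ndarray, np.ndarray],
    rep: AttractorRepertoire,
    times: np.ndarray | None = None,
) -> SymbolicSequence:
    """Nearest-neighbor classification of samples in the product space.

    Each sample (state, G) is assigned the branch of its nearest repertoire
    point; exact distance ties are broken toward the lowest branch id.
    """
    if isinstance(traj, NeuralTrajectory):
        states = np.hstack([traj.S_E, traj.S_I])
        G_values = traj.G_trace
        times = traj.times
    else:
        states, G_values = traj
        if times is None:
            times = np.arange(len(G_values), dtype=float)
    if not rep.points:
        raise ValueError("empty attractor repertoire")
    P = rep.features()
    Q = rep.embed(states, G_values)
    D = cdist(Q, P)
    dmin = D.min(axis=1, keepdims=True)
    tied = D <= dmin + 1e-12 * (1.0 + dmin)
    branches = np.where(tied, rep.branch_id[None, :], np.iinfo(np.int64).max)
    return SymbolicSequence(symbols=branches.min(axis=1), times=np.asarray(times, float))


def build_truth_network(sym: SymbolicSequence) -> TransitionNetwork:
    """Ground-truth transition digraph from a symbolic sequence.

    Nodes are the distinct symbols; a directed edge i -> j exists iff symbol
    i immediately precedes j somewhere in the sequence (i != j).  The node
    measure is the dwell time (member count) normalized to sum 1.
    """
    s = np.asarray(sym.symbols)
    if s.size == 0:
        raise ValueError("empty symbolic sequence")
    g = nx.DiGraph()
    symbols = [int(v) for v in np.unique(s)]
    g.add_nodes_from(symbols)
    for a, b in zip(s[:-1], s[1:]):
        if a != b:
            g.add_edge(int(a), int(b))
    members = {v: np.flatnonzero(s == v) for v in symbols}
    return TransitionNetwork(graph=g, members=members, n_samples=s.size, params={"source": "truth"})


def compute_repertoire(
    conn: Connectome,
    params: ModelParameters | None = None,
    G_min: float = 1.1,
    G_max: float = 5.0,
    G_step: float = 0.01,
    link_threshold: float | None = None,
    G_scaling: float = 1.0,
    tol: float = 1e-9,
    extra_starts: list[np.ndarray] | None = None,
) -> AttractorRepertoire:
    """Fixed points -> stability -> branches, over a uniform G grid.

    ``extra_starts`` supplements the homogeneous start lattice (e.g., with
    module on/off activation patterns for modular connectomes).
    """
    grid = np.arange(G_min, G_max + G_step / 2, G_step)
    fps = find_fixed_points(conn, params, grid, tol=tol, extra_starts=extra_starts)
    for fp in fps:
        classify_stability(fp, conn, params)
    return cluster_attractors(fps, grid, link_threshold=link_threshold, G_scaling=G_scaling)
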