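"""Gromov-Wasserstein third lower bound (TLB) between measure networks.

A measure network is a pair (E, p): an n x n (possibly asymmetric) matrix
of directed geodesic distances and a positive probability vector over the
nodes.  The full GW distance minimizes the quadratic distortion

    d_GW(E, p, F, q)^2 = min_{C in C(p, q)} sum_ijkl (E_ik - F_jl)^2 C_kl C_ij

over couplings C with marginals p and q.  The TLB decouples the two copies
of C:

    TLB^2 = min_{C in C(p, q)} sum_ij J_ij C_ij,
    J_ij = min_{B in C(p, q)} sum_kl (E_ik - F_jl)^2 B_kl,

where each inner problem is a 1-D optimal transport between the weighted
out-distance profiles (E_i., p) and (F_j., q) with squared cost, solved in
closed form by the monotone (quantile) coupling.  The outer problem is an
ordinary transportation linear program, solved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .analytics import geodesic_matrix
from .network import TransitionNetwork

__all__ = [
    "MeasureNetwork",
    "GWResult",
    "to_measure_network",
    "tlb_cost_matrix",
    "solve_tlb",
    "tlb",
]


@dataclass
class MeasureNetwork:
    """(Geodesic matrix, node measure) pair."""

    E: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.p = np.asarray(self.p, dtype=float).ravel()
        if self.E.ndim != 2 or self.E.shape[0] != self.E.shape[1]:
            raise ValueError("E must be square")
        if self.E.shape[0] != self.p.shape[0]:
            raise ValueError("p length must match E")
        if not np.all(np.isfinite(self.E)):
            raise ValueError("E must be finite (strong connectivity or a cap)")
        if np.any(np.diag(self.E) != 0):
            raise ValueError("E must have a zero diagonal")
        if np.any(self.p <= 0):
            raise ValueError("node measures must be strictly positive")
        s = self.p.sum()
        if abs(s - 1.0) > 1e-8:
            raise ValueError("node measure must sum to 1")
        self.p = self.p / s

    @property
    def n_nodes(self) -> int:
        return self.p.size


@dataclass
class GWResult:
    """TLB value, optimal coupling and the inner-problem cost matrix."""

    tlb_squared: float
    coupling: np.ndarray
    cost_matrix: np.ndarray

    @property
    def tlb(self) -> float:
        return float(np.sqrt(max(self.tlb_squared, 0.0)))


def to_measure_network(net: TransitionNetwork, cap: float | None = None) -> MeasureNetwork:
    """Geodesic matrix plus dwell-time measure of a transition network."""
    E = geodesic_matrix(net, cap=cap)
    return MeasureNetwork(E=E, p=net.measure())


def _quantile_sq_transport(
    a: np.ndarray, wa: np.ndarray, b: np.ndarray, wb: np.ndarray
) -> float:
    """Squared-cost 1-D optimal transport between weighted point sets.

    Sorts both profiles and applies the monotone coupling of their
    quantile functions (the north-west-corner rule on sorted supports).
    """
    ia = np.argsort(a, kind="stable")
    ib = np.argsort(b, kind="stable")
    a_s, wa_s = a[ia], wa[ia]
    b_s, wb_s = b[ib], wb[ib]
    ca = np.cumsum(wa_s)
    cb = np.cumsum(wb_s)
    edges = np.unique(np.concatenate([[0.0], ca, cb, [1.0]]))
    mids = 0.5 * (edges[:-1] + edges[1:])
    seg = np.diff(edges)
    qa = a_s[np.minimum(np.searchsorted(ca, mids), a_s.size - 1)]
    qb = b_s[np.minimum(np.searchsorted(cb, mids), b_s.size - 1)]
    return float(np.sum(seg * (qa - qb) ** 2))


def tlb_cost_matrix(A: MeasureNetwork, B: MeasureNetwork) -> np.ndarray:
    """Closed-form inner problems: J_ij is the squared 1-D transport cost
    between the out-distance profiles (E_i., p) and (F_j., q)."""
    n, m = A.n_nodes, B.n_nodes
    J = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            J[i, j] = _quantile_sq_transport(A.E[i], A.p, B.E[j], B.p)
    return J


def solve_transport(J: np.ndarray, p: np.ndarray, q: np.ndarray) -> tuple[float, np.ndarray]:
    """Exact transportation LP: min <J, C> s.t. C 1 = p, C^T 1 = q, C >= 0."""
    n, m = J.shape
    A_eq = []
    b_eq = []
    for i in range(n):
        row = np.zeros(n * m)
        row[i * m : (i + 1) * m] = 1.0
        A_eq.append(row)
        b_eq.append(p[i])
    for j in range(m - 1):  # last column constraint is redundant
        row = np.zeros(n * m)
        row[j::m] = 1.0
        A_eq.append(row)
        b_eq.append(q[j])
    res = linprog(
        J.ravel(),
        A_eq=np.array(A_eq),
        b_eq=np.array(b_eq),
        bounds=(0, None),
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"transportation LP failed: {res.message}")
    C = res.x.reshape(n, m)
    if np.max(np.abs(C.sum(axis=1) - p)) > 1e-9 or np.max(np.abs(C.sum(axis=0) - q)) > 1e-9:
        raise RuntimeError("transport plan violates the marginal constraints")
    return float(res.fun), C


def solve_tlb(A: MeasureNetwork, B: MeasureNetwork) -> GWResult:
    """TLB between two measure networks: closed-form inner costs, exact
    outer linear program.  Returns the squared optimum, its square root,
    and the optimal coupling."""
    J = tlb_cost_matrix(A, B)
    val, C = solve_transport(J, A.p, B.p)
    return GWResult(tlb_squared=val, coupling=C, cost_matrix=J)


def tlb(A: MeasureNetwork | TransitionNetwork, B: MeasureNetwork | TransitionNetwork,
        cap: float | None = None) -> float:
    """Convenience wrapper returning the (square-rooted) TLB distance."""
    if isinstance(A, TransitionNetwork):
        A = to_measure_network(A, cap=cap)
    if isinstance(B, TransitionNetwork):
        B = to_measure_network(B, cap=cap)
    return solve_tlb(A, B).tlb
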