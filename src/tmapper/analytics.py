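"""Analytics on transition networks and time series.

Recurrence plots from directed geodesics or raw state distances, a
sliding-window dynamic-functional-connectivity (dFC) baseline,
source/sink distance profiles, the shortest-path-pair cycle heuristic,
degree- and cycle-based task occupancy, and surrogate (null) time series.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .mapper import pairwise_distances
from .network import TransitionNetwork
from .timeseries import MultivariateTimeSeries

__all__ = [
    "RecurrenceMatrix",
    "CycleSet",
    "geodesic_matrix",
    "recurrence_matrix",
    "dfc_recurrence",
    "source_sink_profiles",
    "enumerate_cycles",
    "degree_occupancy",
    "cycle_occupancy",
    "recurrence_l2",
    "null_models",
    "symbolic_agreement",
]

logger = logging.getLogger(__name__)


@dataclass
class RecurrenceMatrix:
    """T x T matrix of distances between the states at pairs of time points.

    Network mode uses directed block geodesics and may be asymmetric;
    state and dFC modes are symmetric Euclidean distances.
    """

    R: np.ndarray
    mode: str  # 'network' | 'state' | 'dfc'
    times: np.ndarray | None = None
    window: int | None = None


@dataclass
class CycleSet:
    """Simple directed cycles, canonicalized to start at the smallest node."""

    cycles: list[tuple] = field(default_factory=list)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(c) for c in self.cycles], dtype=int)

    def __len__(self) -> int:
        return len(self.cycles)


def geodesic_matrix(
    net: TransitionNetwork | nx.DiGraph,
    cap: float | None = None,
) -> np.ndarray:
    """All-pairs directed hop distances between network nodes.

    Rows/columns follow ``net.node_order()`` (sorted node ids).  The digraph
    must be strongly connected unless ``cap`` supplies a finite distance for
    unreachable ordered pairs.
    """
    graph = net.graph if isinstance(net, TransitionNetwork) else net
    order = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(order)}
    m = len(order)
    D = np.full((m, m), np.inf)
    np.fill_diagonal(D, 0.0)
    for src, dists in nx.all_pairs_shortest_path_length(graph):
        for dst, d in dists.items():
            D[index[src], index[dst]] = d
    if np.any(np.isinf(D)):
        if cap is None:
            i, j = np.argwhere(np.isinf(D))[0]
            raise ValueError(
                "digraph is not strongly connected: no directed path from "
                f"node {order[i]!r} to node {order[j]!r} (set a finite cap to proceed)"
            )
        D[np.isinf(D)] = cap
    return D


def recurrence_matrix(
    source: TransitionNetwork | MultivariateTimeSeries,
    mode: str = "network",
    cap: float | None = None,
) -> RecurrenceMatrix:
    """Per-time-point recurrence plot.

    mode='network': R[t, t'] is the directed geodesic from block(t) to
    block(t') in the transition network (asymmetric in general).
    mode='state': R is the Euclidean distance between raw samples.
    """
    if mode == "network":
        if not isinstance(source, TransitionNetwork):
            raise TypeError("network mode requires a TransitionNetwork")
        G = geodesic_matrix(source, cap=cap)
        blk = source.block_index_of()
        return RecurrenceMatrix(R=G[np.ix_(blk, blk)], mode="network")
    if mode == "state":
        if not isinstance(source, MultivariateTimeSeries):
            raise TypeError("state mode requires a MultivariateTimeSeries")
        return RecurrenceMatrix(
            R=pairwise_distances(source.X), mode="state", times=source.times
        )
    raise ValueError(f"unknown mode {mode!r}")


def dfc_recurrence(
    ts: MultivariateTimeSeries,
    window: int = 30,
    step: int = 1,
) -> RecurrenceMatrix:
    """Sliding-window dFC distance matrix.

    Pearson correlation matrices are computed in windows of ``window`` TRs
    (aligned to their first TR, advancing by ``step``); the lower-triangle
    entries are Fisher-z transformed and the recurrence entry is the
    Euclidean distance between the vectorized windows.  Channels with zero
    variance inside a window contribute zero correlation (with a warning).
    """
    X = ts.X
    T, M = X.shape
    if M < 2:
        raise ValueError("dFC requires at least two channels")
    if T < window:
        raise ValueError(f"need at least window={window} samples (got {T})")
    starts = np.arange(0, T - window + 1, step)
    il = np.tril_indices(M, k=-1)
    vecs = np.empty((len(starts), len(il[0])))
    warned = False
    for w, s in enumerate(starts):
        seg = X[s : s + window]
        sd = seg.std(axis=0)
        bad = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(seg, rowvar=False)
        if np.any(bad):
            C[bad, :] = 0.0
            C[:, bad] = 0.0
            if not warned:
                logger.warning(
                    "zero-variance channel(s) in dFC window starting at %d; "
                    "their correlations are set to 0", s,
                )
                warned = True
        z = np.arctanh(np.clip(C[il], -1 + 1e-12, 1 - 1e-12))
        vecs[w] = z
    R = cdist(vecs, vecs)
    centers = ts.times[starts + window // 2]
    return RecurrenceMatrix(R=R, mode="dfc", times=centers, window=window)


def source_sink_profiles(
    R: RecurrenceMatrix | np.ndarray,
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row means (source distance), column means (sink distance) and their
    difference (sink - source), diagonal excluded.

    With ``normalize=True`` distances are first divided by the maximum
    entry (per-subject normalization).
    """
    A = R.R if isinstance(R, RecurrenceMatrix) else np.asarray(R, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("recurrence matrix must be square")
    if normalize:
        mx = A.max()
        if mx > 0:
            A = A / mx
    n = A.shape[0]
    off = ~np.eye(n, dtype=bool)
    denom = n - 1 if n > 1 else 1
    source = np.where(off, A, 0.0).sum(axis=1) / denom
    sink = np.where(off, A, 0.0).sum(axis=0) / denom
    return source, sink, sink - source


def enumerate_cycles(net: TransitionNetwork | nx.DiGraph) -> CycleSet:
    """Shortest-path-pair cycle heuristic.

    For every node pair, the shortest path i -> j is concatenated with the
    shortest path j -> i (avoiding the repeated endpoints); the result is
    kept only if it is a simple directed cycle.  Rotations of the same cycle
    are deduplicated, keeping the copy that starts at the smallest node.
    Node pairs without a path in either direction are skipped, so the
    heuristic also applies to non-strongly-connected digraphs.  By
    construction the result is a subset of all simple cycles.
    """
    graph = net.graph if isinstance(net, TransitionNetwork) else net
    paths = dict(nx.all_pairs_shortest_path(graph))
    nodes = sorted(graph.nodes)
    seen: set[tuple] = set()
    cycles: list[tuple] = []
    for a_i, i in enumerate(nodes):
        for j in nodes[a_i + 1 :]:
            pij = paths.get(i, {}).get(j)
            pji = paths.get(j, {}).get(i)
            if pij is None or pji is None:
                continue
            cyc = list(pij) + list(pji)[1:-1]
            if len(set(cyc)) != len(cyc):
                continue  # not a simple cycle
            start = cyc.index(min(cyc))
            canon = tuple(cyc[start:] + cyc[:start])
            if canon not in seen:
                seen.add(canon)
                cycles.append(canon)
    return CycleSet(cycles=cycles)


def _node_degrees(graph: nx.DiGraph, kind: str = "total") -> dict:
    if kind == "total":
        return {n: graph.in_degree(n) + graph.out_degree(n) for n in graph.nodes}
    if kind == "in":
        return dict(graph.in_degree())
    if kind == "out":
        return dict(graph.out_degree())
    raise ValueError(f"unknown degree kind {kind!r}")


def _top_degree_nodes(
    net: TransitionNetwork, top_percent: float, degree: str = "total"
) -> list:
    deg = _node_degrees(net.graph, degree)
    n_top = int(np.floor(net.n_nodes * top_percent / 100.0))
    if n_top < 1:
        raise ValueError(
            f"top {top_percent}% of {net.n_nodes} nodes selects no node"
        )
    ranked = sorted(deg, key=lambda n: (-deg[n], n))
    return ranked[:n_top]


def degree_occupancy(
    net: TransitionNetwork,
    labels: np.ndarray,
    top_percent: float,
    degree: str = "total",
) -> pd.Series:
    """Per-label fraction of time points in the top-x% highest-degree nodes.

    Degree defaults to total (in + out) degree of the block digraph; the
    returned fractions sum to 1.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != net.n_samples:
        raise ValueError("labels must cover all member time points")
    top = _top_degree_nodes(net, top_percent, degree)
    pts = np.concatenate([net.members[n] for n in top])
    counts = Counter(labels[pts].tolist())
    total = sum(counts.values())
    return pd.Series(
        {lab: c / total for lab, c in sorted(counts.items())}, name="fraction"
    )


def cycle_occupancy(
    net: TransitionNetwork,
    labels: np.ndarray,
    top_percent: float = 2.0,
    degree: str = "total",
    cycles: CycleSet | None = None,
) -> pd.DataFrame:
    """Label occupancy of cycles through high-degree nodes, binned by length.

    Only cycles intersecting the top-x% highest-degree nodes are counted;
    the member time points of the high-degree nodes themselves are
    excluded.  Rows are cycle lengths, columns labels; each row of
    fractions sums to 1.
    """
    labels = np.asarray(labels)
    if cycles is None:
        cycles = enumerate_cycles(net)
    if len(cycles) == 0:
        return pd.DataFrame()
    top = set(_top_degree_nodes(net, top_percent, degree))
    counts: dict[int, Counter] = {}
    for cyc in cycles.cycles:
        if not top.intersection(cyc):
            continue
        pts = [net.members[n] for n in cyc if n not in top]
        if not pts:
            continue
        lab = labels[np.concatenate(pts)]
        counts.setdefault(len(cyc), Counter()).update(lab.tolist())
    if not counts:
        return pd.DataFrame()
    table = pd.DataFrame(counts).T.sort_index().fillna(0.0)
    table = table.div(table.sum(axis=1), axis=0)
    table.index.name = "cycle_length"
    return table[sorted(table.columns)]


def recurrence_l2(R1, R2) -> float:
    """Entrywise (Frobenius) L2 distance between two recurrence plots."""
    A = R1.R if isinstance(R1, RecurrenceMatrix) else np.asarray(R1, dtype=float)
    B = R2.R if isinstance(R2, RecurrenceMatrix) else np.asarray(R2, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return float(np.linalg.norm(A - B))


def _phase_randomize_channel(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = x.size
    spec = np.fft.rfft(x)
    phases = rng.uniform(0, 2 * np.pi, size=spec.size)
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0  # keep the Nyquist bin real
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n)


def null_models(
    ts: MultivariateTimeSeries,
    method: str = "permute",
    n_surrogates: int = 100,
    seed: int | None = None,
) -> list[MultivariateTimeSeries]:
    """Surrogate time series destroying temporal structure.

    'permute' uniformly shuffles the time indices within each epoch (rows
    move together, so the multiset of samples is preserved);
    'phase_randomize' replaces each channel's Fourier phases with random
    ones (per epoch), preserving the amplitude spectrum.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be at least 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_surrogates):
        if method == "permute":
            perm = np.arange(ts.n_samples)
            for sl in ts.epoch_slices():
                seg = perm[sl]
                rng.shuffle(seg)
                perm[sl] = seg
            X = ts.X[perm]
            labels = None if ts.labels is None else ts.labels[perm]
        elif method == "phase_randomize":
            X = np.empty_like(ts.X)
            for sl in ts.epoch_slices():
                for c in range(ts.n_channels):
                    X[sl, c] = _phase_randomize_channel(ts.X[sl, c], rng)
            labels = None if ts.labels is None else ts.labels.copy()
        else:
            raise ValueError(f"unknown surrogate method {method!r}")
        out.append(
            MultivariateTimeSeries(
                X=X, times=ts.times.copy(), epochs=ts.epochs.copy(), labels=labels
            )
        )
    return out


def symbolic_agreement(net: TransitionNetwork, true_symbols: np.ndarray) -> float:
    """Fraction of time points whose block's majority ground-truth symbol
    matches their own symbol (a purity-style reconstruction score)."""
    true_symbols = np.asarray(true_symbols)
    if true_symbols.shape[0] != net.n_samples:
        raise ValueError("true_symbols must cover all time points")
    correct = 0
    for n, ix in net.members.items():
        vals, cnt = np.unique(true_symbols[ix], return_counts=True)
        correct += int(cnt.max())
    return correct / net.n_samples
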