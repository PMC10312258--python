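"""Temporal Mapper: reciprocal-kNN temporal digraphs and their compression.

The construction turns a multivariate time series into a directed
transition network in two stages:

1. Build a digraph on the time points: a k-nearest-neighbor graph in state
   space, with edges between in-epoch temporal neighbors removed, pruned to
   reciprocal pairs (kept as arc pairs), and finally the arrow of time added
   as directed arcs x_i -> x_{i+1} within each epoch.
2. Compress with a hop-scale delta: time points whose directed geodesic
   distance is at most delta in both directions are merged (connected
   components of the auxiliary mutual-reachability graph), and the block
   digraph inherits every crossing arc.

The result is a small digraph whose nodes approximate attractors and whose
arcs approximate the observed transitions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .network import TransitionNetwork
from .timeseries import MultivariateTimeSeries

__all__ = [
    "TemporalDigraph",
    "pairwise_distances",
    "build_temporal_knn_digraph",
    "compress_digraph",
    "run_temporal_mapper",
    "TemporalMapper",
]


def pairwise_distances(X: np.ndarray, p_norm: float = 2) -> np.ndarray:
    """Symmetric matrix of p-norm distances between sample rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("samples contain non-finite values")
    D = cdist(X, X, metric="minkowski", p=p_norm)
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class TemporalDigraph:
    """The uncompressed digraph on time points.

    Spatial (reciprocal-kNN) edges are stored as arc pairs; temporal arcs
    point from each time index to its in-epoch successor.
    """

    graph: nx.DiGraph
    k: int
    ts: MultivariateTimeSeries

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def spatial_pairs(self) -> set[tuple[int, int]]:
        return {
            (min(u, v), max(u, v))
            for u, v, kind in self.graph.edges(data="kind")
            if kind == "spatial"
        }


def _topk_membership(D: np.ndarray, k: int) -> np.ndarray:
    """Boolean matrix M[i, j] = (j is among the k nearest neighbors of i).

    Self is excluded.  Ties at the k-th distance are broken toward the
    smaller time index (stable argsort).
    """
    T = D.shape[0]
    D = D.copy()
    np.fill_diagonal(D, -1.0)  # self sorts first, then dropped
    order = np.argsort(D, axis=1, kind="stable")
    M = np.zeros((T, T), dtype=bool)
    rows = np.repeat(np.arange(T), k)
    M[rows, order[:, 1 : k + 1].ravel()] = True
    return M


def build_temporal_knn_digraph(
    ts: MultivariateTimeSeries | np.ndarray,
    k: int,
    p_norm: float = 2,
) -> TemporalDigraph:
    """Steps 1-4 of the Temporal Mapper digraph construction.

    (1) kNN graph on the samples; (2) drop edges between in-epoch temporal
    neighbors (x_i, x_{i+1}); (3) keep only reciprocal pairs, as arc pairs;
    (4) add directed temporal arcs x_i -> x_{i+1} within each epoch.
    """
    if not isinstance(ts, MultivariateTimeSeries):
        X = np.asarray(ts, dtype=float)
        ts = MultivariateTimeSeries(X=X, times=np.arange(X.shape[0], dtype=float))
    T = ts.n_samples
    if k < 1:
        raise ValueError("k must be at least 1")
    if k >= T:
        raise ValueError(f"k ({k}) must be smaller than the number of samples ({T})")

    D = pairwise_distances(ts.X, p_norm=p_norm)
    M = _topk_membership(D, k)
    recip = M & M.T

    # in-epoch temporal neighbor pairs are never spatial edges
    adjacent = np.zeros((T, T), dtype=bool)
    for sl in ts.epoch_slices():
        idx = np.arange(sl.start, sl.stop - 1)
        adjacent[idx, idx + 1] = True
        adjacent[idx + 1, idx] = True
    recip &= ~adjacent

    g = nx.DiGraph()
    g.add_nodes_from(range(T))
    ii, jj = np.nonzero(np.triu(recip, 1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        g.add_edge(i, j, kind="spatial")
        g.add_edge(j, i, kind="spatial")
    for sl in ts.epoch_slices():
        for i in range(sl.start, sl.stop - 1):
            g.add_edge(i, i + 1, kind="temporal")
    return TemporalDigraph(graph=g, k=k, ts=ts)


def _directed_hop_distances(graph: nx.DiGraph, order: list) -> np.ndarray:
    """All-pairs directed hop distances (inf where unreachable)."""
    index = {n: i for i, n in enumerate(order)}
    n = len(order)
    rows, cols = [], []
    for u, v in graph.edges:
        rows.append(index[u])
        cols.append(index[v])
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    return shortest_path(adj, method="D", directed=True, unweighted=True)


def compress_digraph(
    g: TemporalDigraph | nx.DiGraph,
    delta: int,
    ts: MultivariateTimeSeries | None = None,
    params: dict | None = None,
) -> TransitionNetwork:
    """Contract mutually delta-close nodes into blocks.

    An auxiliary undirected graph U links x_i and x_j iff the directed
    geodesic distance is <= delta in BOTH directions; the connected
    components of U become the blocks of the transition network.  A block
    arc B_i -> B_j exists iff some arc of the original digraph crosses from
    B_i to B_j; block self-loops are dropped.  Unreachable pairs have
    infinite distance and never merge.  The number of weakly connected
    components is invariant under compression.
    """
    if isinstance(g, TemporalDigraph):
        graph = g.graph
        if ts is None:
            ts = g.ts
        params = dict(params or {}, k=g.k)
    else:
        graph = g
        params = dict(params or {})
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    params["delta"] = delta

    order = sorted(graph.nodes)
    dist = _directed_hop_distances(graph, order)
    mutual = (dist <= delta) & (dist.T <= delta)
    n_blocks, labels = connected_components(
        csr_matrix(mutual), directed=False
    )

    index = {n: i for i, n in enumerate(order)}
    members: dict[int, list[int]] = {b: [] for b in range(n_blocks)}
    for n in order:
        members[labels[index[n]]].append(index[n])

    bg = nx.DiGraph()
    bg.add_nodes_from(range(n_blocks))
    for u, v in graph.edges:
        bu, bv = int(labels[index[u]]), int(labels[index[v]])
        if bu != bv:
            bg.add_edge(bu, bv)

    net = TransitionNetwork(
        graph=bg,
        members={b: np.array(ix, dtype=int) for b, ix in members.items()},
        n_samples=len(order),
        params=params,
    )
    if ts is not None:
        _attach_block_attributes(net, ts)
    return net


def _attach_block_attributes(net: TransitionNetwork, ts: MultivariateTimeSeries) -> None:
    """Per-block mean activation, activation rank, and dominant label."""
    global_mean = ts.X.mean(axis=1)
    order = net.node_order()
    block_means = np.array([global_mean[net.members[b]].mean() for b in order])
    ranks = rankdata(block_means, method="ordinal")
    for b, mean, rank in zip(order, block_means, ranks):
        net.graph.nodes[b]["mean_activation"] = float(mean)
        net.graph.nodes[b]["mean_rank"] = int(rank)
        if ts.labels is not None:
            counts = Counter(ts.labels[net.members[b]].tolist())
            top = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
            # most common label; ties broken lexicographically (largest key wins
            # the count tie, then we normalize to smallest for determinism)
            best = sorted(l for l, c in counts.items() if c == top[1])[0]
            net.graph.nodes[b]["dominant_label"] = best


def run_temporal_mapper(
    ts: MultivariateTimeSeries | np.ndarray,
    k: int = 16,
    delta: int = 10,
    p_norm: float = 2,
) -> TransitionNetwork:
    """End-to-end Temporal Mapper: digraph construction plus compression.

    Defaults (k = 16, delta = 10) suit simulated neural activity sampled at
    fMRI-like rates; empirical fMRI runs typically use k = 5, delta = 2.
    """
    dig = build_temporal_knn_digraph(ts, k=k, p_norm=p_norm)
    return compress_digraph(dig, delta=delta, params={"p_norm": p_norm})


class TemporalMapper(ClusterMixin, BaseEstimator):
    """Attractor-transition-network estimator over time-ordered samples.

    Treats the rows of X as a temporally ordered point cloud, builds the
    reciprocal-kNN temporal digraph, compresses it at hop scale ``delta``
    and exposes the resulting blocks as cluster labels.

    Parameters
    ----------
    k : int, default=16
        Neighbor count of the kNN graph (16 suits simulated neural
        activity; 5 is a typical fMRI choice).
    delta : int, default=10
        Compression scale in hops (10 for simulated activity, 2 for fMRI).
    p_norm : float, default=2
        Minkowski exponent of the state-space metric.

    Attributes
    ----------
    digraph_ : TemporalDigraph
        The uncompressed digraph on time points.
    network_ : TransitionNetwork
        The compressed transition network.
    labels_ : ndarray of shape (T,)
        Block index per time point (position in ``network_.node_order()``).

    Examples
    --------
    >>> import numpy as np
    >>> from tmapper.mapper import TemporalMapper
    >>> X = np.concatenate([np.zeros(50), np.ones(50)])[:, None]
    >>> X = X + 0.01 * np.random.default_rng(0).standard_normal((100, 1))
    >>> tm = TemporalMapper(k=5, delta=2).fit(X)
    >>> tm.network_.n_nodes >= 2
    True
    """

    def __init__(self, k: int = 16, delta: int = 10, p_norm: float = 2):
        self.k = k
        self.delta = delta
        self.p_norm = p_norm

    def fit(self, X, y=None, *, times=None, epochs=None, labels=None):
        """Build the transition network from time-ordered samples.

        X may be a (T, M) array or a MultivariateTimeSeries (in which case
        times/epochs/labels are taken from it).
        """
        if isinstance(X, MultivariateTimeSeries):
            ts = X
        else:
            X = check_array(X, ensure_min_samples=2, ensure_2d=False)
            if X.ndim == 1:
                X = X[:, None]
            ts = MultivariateTimeSeries(
                X=X,
                times=np.arange(X.shape[0], dtype=float) if times is None else times,
                epochs=epochs,
                labels=None if labels is None else np.asarray(labels),
            )
        self.n_features_in_ = ts.n_channels
        self.digraph_ = build_temporal_knn_digraph(ts, k=self.k, p_norm=self.p_norm)
        self.network_ = compress_digraph(
            self.digraph_, delta=self.delta, params={"p_norm": self.p_norm}
        )
        self.labels_ = self.network_.block_index_of()
        return self

    def fit_transform(self, X, y=None, **fit_params):
        """Fit and return the block index of every time point."""
        return self.fit(X, y, **fit_params).labels_

    def score(self, X=None, y=None) -> float:
        """Negative number of blocks (more compression scores higher)."""
        check_is_fitted(self, "network_")
        return -float(self.network_.n_nodes)
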