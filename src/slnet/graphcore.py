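"""Graph substrate: network cleaning, shortest-path distances, the
average-shortest-path-length functional and shortest-path frequency counting.

The screen is built on one scalar functional of a network, the average
shortest path length

    D = (1 / (N(N-1)/2)) * sum_{i>j} d_ij

where d_ij is the hop distance between nodes i and j.  That denominator
assumes a connected graph; once nodes are knocked out the graph may
disconnect, so by default D is taken as the mean over *reachable* unordered
pairs (a strict mode errors on disconnection instead).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path as _sp_shortest_path

from .netio import SlnetError, normalize_symbol

log = logging.getLogger("slnet")

#: marker returned by pair_distance for disconnected pairs
UNREACHABLE = math.inf

#: above this node count the distance engine switches from dense BLAS
#: frontier-BFS to scipy's sparse Dijkstra
_DENSE_LIMIT = 1500


class DegenerateGraphError(SlnetError):
    """Raised when an operation leaves no reachable node pair."""


@dataclass(frozen=True)
class SignalingNetwork:
    """An undirected (by default) simple graph over gene symbols with a
    designated cancer-gene subset.

    The cancer genes must be a subset of the nodes; use
    :meth:`with_cancer_genes` to map an external cancer-gene list onto the
    network (genes absent from the network are dropped with a log message).
    """

    graph: nx.Graph
    cancer_genes: frozenset = frozenset()
    directed: bool = False

    def __post_init__(self):
        extra = set(self.cancer_genes) - set(self.graph.nodes)
        if extra:
            raise SlnetError(
                f"cancer genes not in network: {', '.join(sorted(extra)[:5])}"
            )

    @property
    def N(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def non_cancer_genes(self) -> set:
        return set(self.graph.nodes) - set(self.cancer_genes)

    def with_cancer_genes(self, genes) -> "SignalingNetwork":
        genes = {normalize_symbol(g) for g in genes}
        mapped = genes & set(self.graph.nodes)
        if len(mapped) < len(genes):
            log.info("mapped %d of %d cancer genes onto the network",
                     len(mapped), len(genes))
        return replace(self, cancer_genes=frozenset(mapped))


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def clean_network(net: SignalingNetwork, prune_leaves: bool = False) -> SignalingNetwork:
    """Remove self-loops, collapse duplicate edges, and drop orphan
    (degree-0) nodes.  With ``prune_leaves`` a single, non-iterative pass
    additionally removes degree-1 nodes (the "peripheral" interactions),
    followed by another orphan sweep.

    Idempotent in the default mode.  Raises :class:`DegenerateGraphError`
    if cleaning empties the graph.
    """
    if net.N == 0:
        raise DegenerateGraphError("cannot clean an empty network")
    G = net.graph.copy()
    n_loops = nx.number_of_selfloops(G)
    G.remove_edges_from(nx.selfloop_edges(G))
    orphans = [v for v, d in G.degree() if d == 0]
    G.remove_nodes_from(orphans)
    n_leaves = 0
    if prune_leaves:
        leaves = [v for v, d in G.degree() if d == 1]
        G.remove_nodes_from(leaves)
        n_leaves = len(leaves)
        second_orphans = [v for v, d in G.degree() if d == 0]
        G.remove_nodes_from(second_orphans)
        orphans += second_orphans
    log.info("clean_network: removed %d self-loops, %d orphans, %d leaves",
             n_loops, len(orphans), n_leaves)
    if G.number_of_nodes() == 0:
        raise DegenerateGraphError("cleaning emptied the graph")
    return replace(net, graph=G,
                   cancer_genes=frozenset(set(net.cancer_genes) & set(G.nodes)))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


class DistanceEngine:
    """Batched shortest-path machinery for one network.

    Holds the adjacency structure once and answers all-pairs hop-distance
    queries after removal of an arbitrary node subset.  Dense graphs up to
    ~1500 nodes use a simultaneous frontier BFS driven by BLAS matmuls;
    larger graphs fall back to scipy's sparse Dijkstra.
    """

    def __init__(self, net: SignalingNetwork):
        self.nodes = sorted(net.graph.nodes)
        self.index = {g: i for i, g in enumerate(self.nodes)}
        self.directed = net.directed
        self._dense = len(self.nodes) <= _DENSE_LIMIT
        if self._dense:
            self._adj = nx.to_numpy_array(net.graph, nodelist=self.nodes,
                                          dtype=np.float32)
            np.fill_diagonal(self._adj, 0)  # ignore self-loops for distances
        else:
            self._adj = nx.to_scipy_sparse_array(net.graph, nodelist=self.nodes,
                                                 dtype=np.int8, format="csr")

    def _keep_mask(self, removed) -> np.ndarray:
        keep = np.ones(len(self.nodes), dtype=bool)
        for g in removed:
            try:
                keep[self.index[g]] = False
            except KeyError:
                raise SlnetError(f"unknown node {g!r}") from None
        return keep

    def distance_matrix(self, removed=()) -> tuple[np.ndarray, list]:
        """All-pairs hop distances after deleting ``removed`` nodes.

        Returns ``(D, kept_nodes)`` where D[i, j] is the distance between
        kept_nodes[i] and kept_nodes[j] (inf if unreachable).
        """
        keep = self._keep_mask(removed)
        kept_nodes = [self.nodes[i] for i in np.flatnonzero(keep)]
        if self._dense:
            A = self._adj[np.ix_(keep, keep)]
            D = _dense_apsp(A, directed=self.directed)
        else:
            A = self._adj[keep][:, keep]
            D = _sp_shortest_path(A, method="D", directed=self.directed,
                                  unweighted=True)
        return D, kept_nodes

    def mean_shortest_path(self, removed=(), strict: bool = False) -> float:
        """Average shortest path length over reachable unordered pairs
        (ordered pairs for directed graphs) after deleting ``removed``.

        Raises :class:`DegenerateGraphError` if no pair is reachable, or —
        in strict mode — if any pair is unreachable.
        """
        D, _ = self.distance_matrix(removed)
        n = D.shape[0]
        if n < 2:
            raise DegenerateGraphError("fewer than 2 nodes remain")
        if self.directed:
            vals = D[~np.eye(n, dtype=bool)]
        else:
            vals = D[np.triu_indices(n, k=1)]
        finite = np.isfinite(vals)
        if strict and not finite.all():
            raise DegenerateGraphError("graph is disconnected (strict mode)")
        if not finite.any():
            raise DegenerateGraphError("no reachable node pair remains")
        return float(np.mean(vals[finite], dtype=np.float64))


def _dense_apsp(A: np.ndarray, directed: bool = False) -> np.ndarray:
    """All-pairs hop distances of an unweighted graph via simultaneous
    frontier BFS; each ring of the BFS is one boolean matmul."""
    n = A.shape[0]
    D = np.full((n, n), np.inf, dtype=np.float32)
    np.fill_diagonal(D, 0.0)
    if n == 0:
        return D
    frontier = np.eye(n, dtype=np.float32)
    d = 0
    while True:
        d += 1
        nxt = frontier @ A
        new = (nxt > 0) & np.isinf(D)
        if not new.any():
            break
        D[new] = d
        frontier = new.astype(np.float32)
    return D


def pair_distance(net: SignalingNetwork, a: str, b: str):
    """Hop distance between two nodes; :data:`UNREACHABLE` if no path."""
    for g in (a, b):
        if g not in net.graph:
            raise SlnetError(f"unknown node {g!r}")
    try:
        return nx.shortest_path_length(net.graph, a, b)
    except nx.NetworkXNoPath:
        return UNREACHABLE


def avg_shortest_path_length(net: SignalingNetwork, strict: bool = False) -> float:
    """The average-shortest-path-length functional D of the network: the
    mean hop distance over reachable unordered pairs.  For a connected
    graph this equals sum_{i>j} d_ij / (N(N-1)/2) exactly."""
    if net.N < 2:
        raise DegenerateGraphError("need at least 2 nodes")
    return DistanceEngine(net).mean_shortest_path(strict=strict)


# ---------------------------------------------------------------------------
# Frequency counting
# ---------------------------------------------------------------------------


def path_frequencies(net: SignalingNetwork) -> dict:
    """Count, for every non-cancer gene, the number of (cancer gene,
    non-cancer gene) pairs for which it lies *interior* on at least one
    shortest path between them.

    A node v is interior to some shortest c–g path iff
    d(c, v) + d(v, g) == d(c, g) with v distinct from both endpoints;
    each pair credits a node at most once, regardless of how many shortest
    paths exist.  Unreachable pairs contribute nothing.  The returned
    mapping covers every non-cancer node (zero counts included).
    """
    cancer = sorted(net.cancer_genes)
    if not cancer:
        raise SlnetError("network has no cancer genes labeled")
    non_cancer = sorted(net.non_cancer_genes)
    if not non_cancer:
        raise SlnetError("network has no non-cancer genes")
    eng = DistanceEngine(net)
    D, nodes = eng.distance_matrix()
    idx = {g: i for i, g in enumerate(nodes)}
    nc_idx = np.array([idx[g] for g in non_cancer])
    counts = np.zeros(len(non_cancer), dtype=np.int64)
    d_vv = D[np.ix_(nc_idx, nc_idx)]  # d(v, g) for v, g non-cancer
    for c in cancer:
        dc = D[idx[c]]
        dcg = dc[nc_idx]                      # d(c, g), g non-cancer
        reachable = np.isfinite(dcg)
        with np.errstate(invalid="ignore"):
            on_path = (dc[nc_idx][:, None] + d_vv) == dcg[None, :]
        on_path &= reachable[None, :]
        on_path &= np.isfinite(dc)[nc_idx][:, None]
        on_path &= dc[nc_idx][:, None] > 0          # v != c (and reachable)
        on_path &= ~np.eye(len(non_cancer), dtype=bool)  # v != g
        counts += on_path.sum(axis=1)
    return {g: int(k) for g, k in zip(non_cancer, counts)}


def select_top_fraction(freq: dict, fraction: float) -> list:
    """The top ``ceil(fraction * len(freq))`` genes by count (descending),
    ties broken by symbol ascending."""
    if not freq:
        raise SlnetError("empty frequency table")
    if not (0 < fraction <= 1):
        raise SlnetError(f"fraction must be in (0, 1], got {fraction}")
    ranked = sorted(freq, key=lambda g: (-freq[g], g))
    k = math.ceil(fraction * len(ranked))
    return ranked[:k]


def candidate_pairs(non_cancer, cancer) -> list:
    """Full (cancer, non-cancer) cross product in deterministic
    cancer-major, symbol-sorted order."""
    nc, ca = sorted(set(non_cancer)), sorted(set(cancer))
    if not nc or not ca:
        raise SlnetError("both gene lists must be non-empty")
    overlap = set(nc) & set(ca)
    if overlap:
        raise SlnetError(
            f"gene lists overlap: {', '.join(sorted(overlap)[:5])}"
        )
    return [(c, n) for c in ca for n in nc]
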