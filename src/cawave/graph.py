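"""Lattice cell networks: dense 8-neighbor grids, correlated Gaussian fields,
probabilistic link removal and node holes.

Cells sit on an n x m lattice with 1-based coordinates (i, j).  In the dense
graph every pair of cells at squared Euclidean distance <= 2 is linked (the
4-neighborhood plus diagonals).  Sparse variants are produced by removing
links with node-level probabilities built from a smooth, unit-variance
Gaussian random field, so that poorly connected regions are spatially
clustered rather than scattered; holes remove the nodes in the field's lowest
quantile altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellGraph",
    "GaussianField",
    "build_dense_grid",
    "dense_edge_count",
    "sample_gaussian_field",
    "link_removal_probabilities",
    "sparsify",
    "punch_holes",
]

Node = tuple[int, int]
Edge = tuple[Node, Node]


def _canonical(u: Node, v: Node) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class CellGraph:
    """Undirected graph of cells on an n x m lattice.

    ``nodes`` are 1-based lattice coordinates; ``edges`` hold canonically
    ordered pairs.  ``d`` is the gap-junctional coupling strength (1/s)
    shared by all links.
    """

    n: int
    m: int
    nodes: frozenset[Node]
    edges: frozenset[Edge]
    d: float = 0.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for (u, v) in self.edges:
            if u == v:
                raise ValueError("self-loop")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge {u}-{v} references a missing node")
            if (u[0] - v[0]) ** 2 + (u[1] - v[1]) ** 2 > 2:
                raise ValueError(f"edge {u}-{v} is not an 8-neighbor link")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_list(self) -> list[Node]:
        """Nodes in row-major order (the state layout of the simulator)."""
        return sorted(self.nodes)

    def node_index(self) -> dict[Node, int]:
        return {v: k for k, v in enumerate(self.node_list())}

    def edge_index_array(self) -> np.ndarray:
        """(|E|, 2) int array of node indices, rows sorted, for vector math."""
        idx = self.node_index()
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        arr = np.array(sorted((idx[u], idx[v]) for u, v in self.edges),
                       dtype=np.int64)
        return arr

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for a, b in self.edge_index_array():
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def with_coupling(self, d: float) -> "CellGraph":
        return CellGraph(self.n, self.m, self.nodes, self.edges, d, dict(self.meta))


def dense_edge_count(n: int, m: int) -> int:
    """Closed-form edge count of the dense grid: n(m-1) + (n-1)m + 2(n-1)(m-1)."""
    return n * (m - 1) + (n - 1) * m + 2 * (n - 1) * (m - 1)


def build_dense_grid(n: int, m: int, d: float = 0.0) -> CellGraph:
    """The fully dense lattice graph: 4-neighbors plus both diagonals."""
    if n < 1 or m < 1:
        raise ValueError("grid dimensions must be >= 1")
    nodes = frozenset((i, j) for i in range(1, n + 1) for j in range(1, m + 1))
    edges = set()
    steps = ((0, 1), (1, 0), (1, 1), (1, -1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            for di, dj in steps:
                u, v = (i, j), (i + di, j + dj)
                if v in nodes:
                    edges.add(_canonical(u, v))
    return CellGraph(n, m, nodes, frozenset(edges), d, {"topology": "dense"})


@dataclass(frozen=True)
class GaussianField:
    """A zero-mean, unit-variance Gaussian field on the lattice nodes.

    Correlation between nodes at Euclidean distance r is exp(-r^2 / c0) with
    c0 = sqrt(n^2 + m^2), i.e. the field is smooth on the scale of the grid.
    """

    n: int
    m: int
    nodes: tuple[Node, ...]
    values: np.ndarray
    c0: float

    def value_map(self) -> dict[Node, float]:
        return dict(zip(self.nodes, self.values))

    def as_matrix(self) -> np.ndarray:
        out = np.full((self.n, self.m), np.nan)
        for (i, j), val in zip(self.nodes, self.values):
            out[i - 1, j - 1] = val
        return out


def _field_covariance(coords: np.ndarray, c0: float) -> np.ndarray:
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / c0)


def sample_gaussian_field(n: int, m: int, seed=None) -> GaussianField:
    """Draw one spatially correlated Gaussian field on the n x m lattice.

    Sampling is by exact Cholesky factorization of the squared-exponential
    covariance (a tiny diagonal jitter keeps the factorization stable), which
    is affordable at the grid sizes used here (<= a few thousand nodes).
    """
    if n < 1 or m < 1:
        raise ValueError("grid dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = tuple((i, j) for i in range(1, n + 1) for j in range(1, m + 1))
    coords = np.array(nodes, dtype=float)
    c0 = float(np.hypot(n, m))
    cov = _field_covariance(coords, c0)
    cov[np.diag_indices_from(cov)] += 1e-10
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "field covariance is not positive definite after jitter") from exc
    z = rng.standard_normal(len(nodes))
    return GaussianField(n, m, nodes, chol @ z, c0)


def link_removal_probabilities(field_: GaussianField, p: float) -> dict[Node, float]:
    """Node-level removal probabilities p(v) = p * (max F - F(v)) / (max F - min F).

    Nodes in field troughs get probability p (sparse regions); nodes at the
    field crest get 0 (densely linked regions).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    fmax = float(np.max(field_.values))
    fmin = float(np.min(field_.values))
    if fmax == fmin:
        raise ValueError("constant field: removal probabilities undefined")
    scale = p / (fmax - fmin)
    return {v: scale * (fmax - val) for v, val in zip(field_.nodes, field_.values)}


_EDGE_RULES = {
    "mean": lambda pu, pv: 0.5 * (pu + pv),
    "min": min,
    "max": max,
    "first": lambda pu, pv: pu,
}


def sparsify(graph: CellGraph, prob_map: dict[Node, float], seed=None,
             rule: str = "mean") -> CellGraph:
    """Remove each link independently using its endpoints' probabilities.

    The source material assigns the removal probability to a *node*; how a
    link between two nodes inherits it is ambiguous, so the endpoint
    combination is configurable (default: symmetric mean) and recorded in
    the graph metadata.
    """
    if rule not in _EDGE_RULES:
        raise ValueError(f"unknown edge rule {rule!r}")
    combine = _EDGE_RULES[rule]
    missing = [v for v in graph.nodes if v not in prob_map]
    if missing:
        raise ValueError(f"prob_map missing {len(missing)} nodes, e.g. {missing[0]}")
    rng = np.random.default_rng(seed)
    edges = sorted(graph.edges)
    draws = rng.random(len(edges))
    kept = frozenset(e for e, r in zip(edges, draws)
                     if r >= combine(prob_map[e[0]], prob_map[e[1]]))
    meta = dict(graph.meta)
    meta.update(topology="sparsified", edge_rule=rule,
                removed_edges=len(edges) - len(kept))
    return CellGraph(graph.n, graph.m, graph.nodes, kept, graph.d, meta)


def punch_holes(graph: CellGraph, field_: GaussianField, q_quantile: float) -> CellGraph:
    """Remove nodes whose field value lies strictly below the empirical
    q-quantile of F (linear-interpolation convention), with incident edges."""
    if not 0.0 <= q_quantile < 1.0:
        raise ValueError("q_quantile must lie in [0, 1)")
    if q_quantile == 0.0:
        return graph
    threshold = float(np.quantile(field_.values, q_quantile))
    fmap = field_.value_map()
    keep = frozenset(v for v in graph.nodes if fmap[v] >= threshold)
    edges = frozenset(e for e in graph.edges if e[0] in keep and e[1] in keep)
    meta = dict(graph.meta)
    meta.update(topology="holes", hole_quantile=q_quantile,
                removed_nodes=graph.n_nodes - len(keep))
    return CellGraph(graph.n, graph.m, keep, edges, graph.d, meta)
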