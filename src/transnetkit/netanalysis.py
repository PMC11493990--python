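"""Topological analysis of trans-omics networks.

Global metrics (degree distribution, density D = 2E/(N(N-1)), clustering
C_u = 2T(u)/(D(u)(D(u)-1)), assortativity, mean degree) are computed on the
simple undirected projection of the multilayer graph — parallel edges of
different types, edge direction and self-loops do not enter the counts.
The scaling parameter gamma of an approximately power-law (majority-leaves
minority-hubs) degree distribution N_k ∝ k^(-gamma) is estimated by
ordinary least squares on log10(N_k) vs log10(k); least-squares estimates
of power-law exponents are known to be imprecise and the confidence
interval should be read with that caveat.

Signed motif extraction (feedback cycles and feedforward loops) operates on
the directed edges, with PPI edges treated as bidirectional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import stats as sps

from .graph_core import EdgeType, Sign, TransOmicsNetwork

__all__ = [
    "DegreeDistribution",
    "ScalingFit",
    "LoopRecord",
    "degree",
    "degree_centrality",
    "degree_distribution",
    "fit_scaling_parameter",
    "density",
    "mean_degree",
    "clustering_coefficient",
    "average_clustering",
    "assortativity",
    "rank_by_degree",
    "find_feedback_loops",
    "find_feedforward_loops",
]


@dataclass(frozen=True)
class DegreeDistribution:
    """Histogram (k, N_k) of positive degrees plus the zero-degree count;
    sum(N_k) + n_zero == N."""

    pairs: Tuple[Tuple[int, int], ...]
    n_nodes: int
    n_zero_degree: int

    def __post_init__(self) -> None:
        ks = [k for k, _ in self.pairs]
        if ks != sorted(set(ks)):
            raise ValueError("k values must be strictly increasing")
        if sum(nk for _, nk in self.pairs) + self.n_zero_degree != self.n_nodes:
            raise ValueError("degree histogram does not conserve node count")


@dataclass(frozen=True)
class ScalingFit:
    """Least-squares estimate of the scaling parameter gamma."""

    gamma: float
    gamma_ci95: Tuple[float, float]
    r_squared: float
    n_points: int
    intercept: float
    log_base: int = 10


@dataclass(frozen=True)
class LoopRecord:
    """A feedback cycle (node sequence, first node not repeated) or a
    feedforward triple (x, y, z) with edges x→y, y→z, x→z."""

    nodes: Tuple
    loop_type: str  # "feedback" | "feedforward"
    sign: str  # feedback: positive/negative/unsigned; FFL: coherent/incoherent/unsigned


def _projection(net) -> nx.Graph:
    if isinstance(net, TransOmicsNetwork):
        return net.to_simple_undirected()
    if isinstance(net, nx.Graph) and not net.is_directed() and not net.is_multigraph():
        return net
    return nx.Graph(net)


def degree(net, node) -> int:
    g = _projection(net)
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    return int(g.degree(node))


def degree_centrality(net, node) -> float:
    """k/(N-1): the node's degree normalized by the maximum possible."""
    g = _projection(net)
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    if g.number_of_nodes() < 2:
        raise ValueError("degree centrality requires at least 2 nodes")
    return g.degree(node) / (g.number_of_nodes() - 1)


def degree_distribution(net) -> DegreeDistribution:
    g = _projection(net)
    if g.number_of_nodes() < 1:
        raise ValueError("degree distribution requires at least one node")
    degrees = [d for _, d in g.degree()]
    n_zero = sum(1 for d in degrees if d == 0)
    counts: dict[int, int] = {}
    for d in degrees:
        if d > 0:
            counts[d] = counts.get(d, 0) + 1
    pairs = tuple(sorted(counts.items()))
    return DegreeDistribution(pairs=pairs, n_nodes=len(degrees), n_zero_degree=n_zero)


def fit_scaling_parameter(dist: DegreeDistribution) -> ScalingFit:
    """OLS fit of log10(N_k) on log10(k) over k with N_k > 0; gamma is the
    negated slope and the 95% CI comes from the t-based slope standard
    error."""
    points = [(k, nk) for k, nk in dist.pairs if nk > 0]
    if len(points) < 3:
        raise ValueError("scaling fit requires at least 3 distinct degrees")
    x = np.log10([k for k, _ in points])
    y = np.log10([nk for _, nk in points])
    fit = sps.linregress(x, y)
    n = len(points)
    tcrit = sps.t.ppf(0.975, n - 2)
    gamma = -fit.slope
    half = tcrit * fit.stderr if np.isfinite(fit.stderr) else 0.0
    return ScalingFit(
        gamma=float(gamma),
        gamma_ci95=(float(gamma - half), float(gamma + half)),
        r_squared=float(fit.rvalue**2),
        n_points=n,
        intercept=float(fit.intercept),
    )


def density(net) -> float:
    """D = 2E/(N(N-1)) on the simple undirected projection."""
    g = _projection(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def mean_degree(net) -> float:
    g = _projection(net)
    if g.number_of_nodes() < 1:
        raise ValueError("mean degree requires at least one node")
    return 2.0 * g.number_of_edges() / g.number_of_nodes()


def clustering_coefficient(net, node) -> float:
    """C_u = 2T(u)/(D(u)(D(u)-1)); 0 by convention when D(u) < 2."""
    g = _projection(net)
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    return float(nx.clustering(g, node))


def average_clustering(net) -> float:
    g = _projection(net)
    if g.number_of_nodes() < 1:
        raise ValueError("average clustering requires at least one node")
    return float(nx.average_clustering(g))


def assortativity(net) -> float:
    """Degree assortativity: Pearson correlation of endpoint degrees over
    all edges, both orientations included.  Undefined (error) when endpoint
    degrees have zero variance (e.g. regular graphs)."""
    g = _projection(net)
    if g.number_of_edges() < 1:
        raise ValueError("assortativity requires at least one edge")
    deg = dict(g.degree())
    xs, ys = [], []
    for u, v in g.edges():
        xs.extend((deg[u], deg[v]))
        ys.extend((deg[v], deg[u]))
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("assortativity undefined: endpoint degrees have zero variance")
    return float(np.corrcoef(xs, ys)[0, 1])


def rank_by_degree(net, top_n: int) -> list:
    """Top-``top_n`` (node, degree) pairs, descending by degree with
    deterministic lexicographic tie-breaking by node id."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    g = _projection(net)
    ranked = sorted(g.degree(), key=lambda kv: (-kv[1], _node_sort_key(kv[0])))
    return ranked[:top_n]


def _node_sort_key(node):
    if isinstance(node, tuple):
        return tuple(str(p) for p in node)
    return (str(node),)


# ---------------------------------------------------------------------------
# signed motif extraction
# ---------------------------------------------------------------------------

def _signed_digraph(net) -> nx.DiGraph:
    """Directed simple view with a per-(u, v) consensus sign.

    PPI edges enter in both directions (they are bidirectional by
    convention).  When parallel edges of different types disagree on sign,
    the pair is marked unsigned.
    """
    if isinstance(net, nx.DiGraph) and not net.is_multigraph():
        g = nx.DiGraph()
        g.add_nodes_from(net.nodes())
        for u, v, data in net.edges(data=True):
            _accumulate_sign(g, u, v, data.get("sign", Sign.UNSIGNED.value))
        return g
    if not isinstance(net, TransOmicsNetwork):
        raise TypeError("expected TransOmicsNetwork or DiGraph")
    g = nx.DiGraph()
    g.add_nodes_from(net.node_keys)
    for edge in net.edges:
        _accumulate_sign(g, edge.source, edge.target, edge.sign.value)
        if edge.edge_type is EdgeType.PPI:
            _accumulate_sign(g, edge.target, edge.source, edge.sign.value)
    return g


def _accumulate_sign(g: nx.DiGraph, u, v, sign: str) -> None:
    if g.has_edge(u, v):
        if g[u][v]["sign"] != sign:
            g[u][v]["sign"] = Sign.UNSIGNED.value
    else:
        g.add_edge(u, v, sign=sign)


def find_feedback_loops(net, max_len: int = 5) -> list[LoopRecord]:
    """All simple directed cycles of length 2..``max_len``.

    Sign parity rule: a fully signed cycle is positive when it contains an
    even number of inhibiting edges and negative when odd; any unsigned
    edge makes the loop unsigned.  Cycles are reported with a canonical
    rotation (smallest node first) for determinism.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    g = _signed_digraph(net)
    records = []
    for cycle in nx.simple_cycles(g, length_bound=max_len):
        if len(cycle) < 2:
            continue
        start = min(range(len(cycle)), key=lambda i: _node_sort_key(cycle[i]))
        cycle = cycle[start:] + cycle[:start]
        signs = [g[u][v]["sign"] for u, v in zip(cycle, cycle[1:] + cycle[:1])]
        if Sign.UNSIGNED.value in signs:
            sign = "unsigned"
        else:
            n_inhibit = sum(1 for s in signs if s == Sign.INHIBITING.value)
            sign = "positive" if n_inhibit % 2 == 0 else "negative"
        records.append(LoopRecord(nodes=tuple(cycle), loop_type="feedback", sign=sign))
    records.sort(key=lambda r: tuple(map(_node_sort_key, r.nodes)))
    return records


def find_feedforward_loops(net) -> list[LoopRecord]:
    """All feedforward triples (x, y, z) with edges x→y, y→z, x→z.

    Coherent iff the sign of the direct edge x→z equals the product of the
    signs along x→y→z (activating = +1, inhibiting = −1); unsigned if any
    of the three edges is unsigned.
    """
    g = _signed_digraph(net)
    records = []
    for x in g.nodes():
        for y in g.successors(x):
            if y == x:
                continue
            for z in g.successors(y):
                if z == x or z == y or not g.has_edge(x, z):
                    continue
                s_xy = g[x][y]["sign"]
                s_yz = g[y][z]["sign"]
                s_xz = g[x][z]["sign"]
                if Sign.UNSIGNED.value in (s_xy, s_yz, s_xz):
                    sign = "unsigned"
                else:
                    path = (-1) ** sum(
                        s == Sign.INHIBITING.value for s in (s_xy, s_yz)
                    )
                    direct = -1 if s_xz == Sign.INHIBITING.value else 1
                    sign = "coherent" if path == direct else "incoherent"
                records.append(
                    LoopRecord(nodes=(x, y, z), loop_type="feedforward", sign=sign)
                )
    records.sort(key=lambda r: tuple(map(_node_sort_key, r.nodes)))
    return records
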