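"""Topological and morphometric statistics of vascular graphs.

Topology follows the standard small-world analysis: local clustering
C_i = 2E_i / (k_i (k_i - 1)), its vertex average C, the characteristic
path length L (mean shortest-path hop distance over vertex pairs), and
the small-worldness index

    sigma = (C / C_r) / (L / L_r),

where C_r and L_r are ensemble means over equivalent random graphs with
the same number of vertices and edges (uniform G(n, m) null).  sigma > 1
is read as evidence of small-world structure.

Morphometry (mean edge length/thickness, edge-length histograms) is
computed over the full edge table including self-loops and parallel
edges; topology uses the simplified graph (self-loops dropped, parallel
edges collapsed).  Undefined quantities (empty graphs, C_r = 0, L on a
single vertex) propagate as NaN, never as exceptions.
"""

from __future__ import annotations

import dataclasses
import math

import networkx as nx
import numpy as np
from scipy.sparse import csgraph

from .graph import VascularGraph

__all__ = [
    "NetworkMetrics",
    "to_simple_graph",
    "local_clustering",
    "mean_clustering",
    "characteristic_path_length",
    "small_worldness",
    "edge_statistics",
    "edge_length_histogram",
    "compute_metrics",
]


@dataclasses.dataclass
class NetworkMetrics:
    """Per-graph summary; NaN marks undefined values."""

    n_vertices: int
    n_edges: int
    mean_clustering: float
    char_path_length: float
    sigma: float
    c_random: float
    l_random: float
    n_random_reps: int
    mean_edge_length: float
    mean_edge_thickness: float
    lcc_fraction: float


def to_simple_graph(graph) -> nx.Graph:
    """Simple undirected view: drop self-loops, collapse parallel edges;
    the vertex set is unchanged.  Idempotent on already-simple graphs."""
    g = graph.g if isinstance(graph, VascularGraph) else graph
    simple = nx.Graph(g)
    simple.remove_edges_from(nx.selfloop_edges(simple))
    return simple


def local_clustering(graph, vertex) -> float:
    """C_i = 2 E_i / (k_i (k_i - 1)); 0 by convention when k_i < 2."""
    g = to_simple_graph(graph)
    if vertex not in g:
        raise KeyError(f"vertex {vertex!r} not in graph")
    return float(nx.clustering(g, vertex))


def mean_clustering(graph) -> float:
    """Arithmetic mean of C_i over all vertices (k_i < 2 contribute 0);
    NaN on the empty graph."""
    g = to_simple_graph(graph)
    if g.number_of_nodes() == 0:
        return float("nan")
    return float(nx.average_clustering(g, count_zeros=True))


def characteristic_path_length(graph) -> float:
    """Mean hop distance over all unordered vertex pairs of the largest
    connected component; NaN when that component has < 2 vertices."""
    g = to_simple_graph(graph)
    if g.number_of_nodes() == 0:
        return float("nan")
    lcc = max(nx.connected_components(g), key=len)
    n = len(lcc)
    if n < 2:
        return float("nan")
    adj = nx.to_scipy_sparse_array(g.subgraph(lcc), format="csr")
    dist = csgraph.shortest_path(adj, method="D", unweighted=True,
                                 directed=False)
    return float(dist[np.triu_indices(n, 1)].mean())


def lcc_fraction(graph) -> float:
    g = to_simple_graph(graph)
    n = g.number_of_nodes()
    if n == 0:
        return float("nan")
    return max(len(c) for c in nx.connected_components(g)) / n


def small_worldness(graph, n_reps: int = 20, seed: int = 0):
    """sigma = (C/C_r)/(L/L_r) against a seeded ensemble of ``n_reps``
    equivalent G(n, m) random graphs.  Returns ``(sigma, c_r, l_r)``;
    sigma is NaN whenever C_r = 0 or L or L_r is undefined."""
    from .synthetic import generate_equivalent_random

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    g = to_simple_graph(graph)
    n, m = g.number_of_nodes(), g.number_of_edges()
    c = mean_clustering(g)
    l = characteristic_path_length(g)
    if n == 0:
        return float("nan"), float("nan"), float("nan")

    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2 ** 31)
    cs, ls = [], []
    for s in child_seeds:
        rand = generate_equivalent_random(n, m, int(s))
        cs.append(mean_clustering(rand))
        ls.append(characteristic_path_length(rand))
    c_r = float(np.mean(cs))
    ls = [x for x in ls if math.isfinite(x)]
    l_r = float(np.mean(ls)) if ls else float("nan")

    if c_r <= 0 or not math.isfinite(l) or not math.isfinite(l_r) or l_r == 0:
        sigma = float("nan")
    else:
        sigma = (c / c_r) / (l / l_r)
    return sigma, c_r, l_r


def edge_statistics(graph: VascularGraph):
    """(mean length, mean thickness, n_edges, n_vertices) over the full
    edge table, self-loops and parallel edges included; zeros on the
    empty graph."""
    n_e, n_v = graph.n_edges, graph.n_vertices
    if n_e == 0:
        return 0.0, 0.0, 0, n_v
    lengths = graph.edge_lengths()
    thicks = graph.edge_thicknesses()
    mean_thick = float(np.nanmean(thicks)) if np.isfinite(thicks).any() else float("nan")
    return float(lengths.mean()), mean_thick, n_e, n_v


def edge_length_histogram(graph: VascularGraph, bin_width: float,
                          max_length: float) -> np.ndarray:
    """Edge counts per half-open bin [k·w, (k+1)·w) up to ``max_length``,
    with a final overflow bin; the counts sum to n_edges."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(max_length / bin_width))
    edges = np.append(np.arange(n_bins + 1) * bin_width, np.inf)
    lengths = graph.edge_lengths()
    counts, _ = np.histogram(lengths, bins=edges)
    return counts


def compute_metrics(graph: VascularGraph, n_random: int = 20,
                    seed: int = 0) -> NetworkMetrics:
    """Full per-graph summary combining topology and morphometry."""
    mean_len, mean_thick, n_e, n_v = edge_statistics(graph)
    c = mean_clustering(graph)
    l = characteristic_path_length(graph)
    sigma, c_r, l_r = small_worldness(graph, n_reps=n_random, seed=seed)
    return NetworkMetrics(
        n_vertices=n_v, n_edges=n_e, mean_clustering=c, char_path_length=l,
        sigma=sigma, c_random=c_r, l_random=l_r, n_random_reps=n_random,
        mean_edge_length=mean_len, mean_edge_thickness=mean_thick,
        lcc_fraction=lcc_fraction(graph))
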