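"""Local and global complexity measures of (cumulative) recurrence networks.

Local, per-vertex measures: degree k_i, degree density rho_i = k_i/(N-1)
(a localized recurrence rate), local clustering C_i (geometric alignment of
state vectors), closeness c_i (inverse arithmetic mean of shortest path
lengths) and local efficiency e_i (inverse geometric mean; a harmonic
variant is available).  Global measures average the local ones: edge density
rho = mean(rho_i) (equal to the recurrence rate of the eps-RN), global
clustering C = mean(C_i), network transitivity T = 3 * triangles / triples,
average path length L = mean(1/c_i) and global efficiency E = 1/mean(e_i).

Vertices that cannot reach part of the network — common in eps-RNs, where a
state need not recur everywhere — are assigned a path length of N - 1 to
every unreachable vertex, so closeness is floored at 1/(N-1).

On directed cumulative networks (``directed_mode='out'``) only out-edges
count: degrees and neighborhoods come from edges into the past, paths follow
edge directions, and inter-neighbor links in the clustering numerator are
evaluated on the symmetrized adjacency so the coefficient stays a fraction
of closed pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _cs_shortest_path

from .recurrence import CumulativeRN

__all__ = [
    "LocalMeasures",
    "GlobalMeasures",
    "local_degree",
    "local_clustering",
    "shortest_paths",
    "local_closeness_efficiency",
    "local_strength",
    "compute_local",
    "global_measures",
]


@dataclass
class LocalMeasures:
    """Per-vertex network measures, index-aligned with time order."""

    degree: np.ndarray
    degree_density: np.ndarray
    clustering: np.ndarray
    closeness: np.ndarray
    efficiency: np.ndarray
    strength: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """One row per node (1-based time index), mirroring the CSV export."""
        return pd.DataFrame(
            {
                "node": np.arange(1, self.degree.size + 1),
                "degree": self.degree,
                "degree_density": self.degree_density,
                "clustering": self.clustering,
                "closeness": self.closeness,
                "efficiency": self.efficiency,
                "strength": self.strength,
            }
        )


@dataclass
class GlobalMeasures:
    edge_density: float
    global_clustering: float
    transitivity: float
    avg_path_length: float
    global_efficiency: float

    def to_frame(self, label: str = "graph") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "graph": [label],
                "edge_density": [self.edge_density],
                "global_clustering": [self.global_clustering],
                "transitivity": [self.transitivity],
                "avg_path_length": [self.avg_path_length],
                "global_efficiency": [self.global_efficiency],
            }
        )


def _unwrap(graph):
    return graph.graph if isinstance(graph, CumulativeRN) else graph


def _adjacency(graph) -> tuple[np.ndarray, bool]:
    """Binary adjacency in node-sorted order plus a directedness flag."""
    g = _unwrap(graph)
    a = nx.to_numpy_array(g, nodelist=sorted(g.nodes), weight=None)
    np.fill_diagonal(a, 0)
    return a.astype(bool), g.is_directed()


def local_degree(graph, directed_mode: str = "all") -> tuple[np.ndarray, np.ndarray]:
    """Degree and degree density per vertex.

    ``directed_mode='out'`` counts out-edges only (cumulative semantics);
    ``'all'`` counts every incident edge.
    """
    a, directed = _adjacency(graph)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least two nodes")
    if directed_mode == "out" or not directed:
        k = a.sum(axis=1)
    elif directed_mode == "all":
        k = a.sum(axis=1) + a.sum(axis=0)
    else:
        raise ValueError("directed_mode must be 'all' or 'out'")
    return k.astype(float), k / (n - 1)


def local_clustering(graph, directed_mode: str = "all") -> np.ndarray:
    """Fraction of neighbor pairs of each vertex that are themselves linked.

    C_i = sum_{j,h} A_ij A_ih S_jh / (k_i (k_i - 1)), where the neighborhood
    rows A come from out-edges when ``directed_mode='out'`` and S is the
    symmetrized adjacency; C_i := 0 for k_i < 2.
    """
    a, directed = _adjacency(graph)
    s = (a | a.T).astype(float)
    if directed and directed_mode == "out":
        nbr = a.astype(float)
    else:
        nbr = s
    k = nbr.sum(axis=1)
    closed = np.einsum("ij,jh,ih->i", nbr, s, nbr)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, closed / np.where(denom > 0, denom, 1), 0.0)
    return c


def shortest_paths(graph) -> np.ndarray:
    """Unweighted shortest-path hop counts with the N-1 disconnection floor.

    Directed graphs are traversed along edge directions.  Unreachable pairs
    are assigned a path length of N - 1.
    """
    a, directed = _adjacency(graph)
    n = a.shape[0]
    l = _cs_shortest_path(csr_matrix(a), method="D", directed=directed, unweighted=True)
    l[np.isinf(l)] = n - 1
    np.fill_diagonal(l, 0.0)
    return l


def local_closeness_efficiency(
    l: np.ndarray, efficiency: str = "geometric"
) -> tuple[np.ndarray, np.ndarray]:
    """Closeness and local efficiency from a path-length matrix.

    closeness_i = [mean_j l_ij]^-1 over j != i; efficiency_i is the inverse
    geometric mean of the same lengths, or the harmonic mean of 1/l_ij with
    ``efficiency='harmonic'``.
    """
    if efficiency not in ("geometric", "harmonic"):
        raise ValueError("efficiency must be 'geometric' or 'harmonic'")
    n = l.shape[0]
    off = ~np.eye(n, dtype=bool)
    lens = l[off].reshape(n, n - 1)
    closeness = 1.0 / lens.mean(axis=1)
    if efficiency == "geometric":
        eff = np.exp(-np.log(lens).mean(axis=1))
    else:
        eff = (1.0 / lens).mean(axis=1)
    return closeness, eff


def local_strength(graph) -> np.ndarray:
    """Sum of incident edge weights; out-strength on directed graphs."""
    g = _unwrap(graph)
    nodes = sorted(g.nodes)
    if g.is_directed():
        deg = g.out_degree(weight="weight")
    else:
        deg = g.degree(weight="weight")
    return np.array([deg[v] for v in nodes], dtype=float)


def compute_local(
    graph, directed_mode: str = "all", efficiency: str = "geometric"
) -> LocalMeasures:
    """All local measures of a graph in one pass."""
    k, rho = local_degree(graph, directed_mode)
    c = local_clustering(graph, directed_mode)
    l = shortest_paths(graph)
    clo, eff = local_closeness_efficiency(l, efficiency)
    s = local_strength(graph)
    return LocalMeasures(
        degree=k, degree_density=rho, clustering=c, closeness=clo, efficiency=eff, strength=s
    )


def global_measures(
    graph, directed_mode: str = "all", efficiency: str = "geometric"
) -> GlobalMeasures:
    """Whole-network summaries as averages of the local measures."""
    local = compute_local(graph, directed_mode, efficiency)
    a, _ = _adjacency(graph)
    sym = nx.from_numpy_array(a | a.T)
    return GlobalMeasures(
        edge_density=float(local.degree_density.mean()),
        global_clustering=float(local.clustering.mean()),
        transitivity=float(nx.transitivity(sym)),
        avg_path_length=float((1.0 / local.closeness).mean()),
        global_efficiency=float(1.0 / local.efficiency.mean()),
    )
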