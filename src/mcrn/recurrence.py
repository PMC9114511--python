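"""Recurrence matrices and (cumulative) recurrence networks.

A multivariate series is read as a trajectory through an m-dimensional phase
space: row i is the state vector y_i observed at time i.  Two time points
recur when their state vectors lie within a distance ``epsilon`` of each
other, which turns the series into a binary recurrence matrix

    R_ij = Theta(epsilon - ||y_i - y_j||),   i != j,

the adjacency matrix of an undirected, simple epsilon-recurrence network
(eps-RN).  Zeroing the upper triangle instead yields a *cumulative*
recurrence network (cRN): a directed graph whose edges point only toward
earlier time points, weighted by the recurrence time i - j, so that every
vertex property can be evaluated using past observations only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "RecurrenceMatrix",
    "CumulativeRN",
    "distance_matrix",
    "epsilon_for_target_rr",
    "recurrence_matrix",
    "build_crn",
    "build_ern",
    "write_graphml",
    "write_edgelist_csv",
]

#: mapping from the user-facing norm names to scipy metric names
_NORMS = {"euclidean": "euclidean", "chebyshev": "chebyshev", "manhattan": "cityblock"}


@dataclass(frozen=True)
class DistanceMatrix:
    """Dense pairwise distance matrix over phase-space coordinates."""

    D: np.ndarray
    norm: str

    @property
    def n(self) -> int:
        return self.D.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) distances as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.D[iu]


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Thresholded recurrence matrix with its achieved recurrence rate."""

    R: np.ndarray  # boolean, symmetric, zero diagonal
    epsilon: float
    recurrence_rate: float

    @property
    def n(self) -> int:
        return self.R.shape[0]


@dataclass
class CumulativeRN:
    """Directed recurrence network with edges toward the past only.

    Edge i -> j exists for every recurrent pair with j < i; the weight is the
    recurrence time i - j (in samples) unless a distance-weight variant was
    requested.  Node indices are 0-based time order internally; exports are
    1-based.
    """

    graph: nx.DiGraph
    epsilon: float
    weight_kind: str = "time"
    _lower: np.ndarray = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def out_degrees(self) -> np.ndarray:
        return self._lower.sum(axis=1)

    def out_strengths(self) -> np.ndarray:
        n = self.n_nodes
        lag = np.arange(n)[:, None] - np.arange(n)[None, :]
        return (self._lower * lag).sum(axis=1).astype(float)


def _as_coordinates(series) -> np.ndarray:
    """Accept a MultivariateSeries, DataFrame or ndarray of state vectors."""
    values = getattr(series, "values", series)
    values = getattr(values, "values", values)  # DataFrame -> ndarray
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("state coordinates must form a 2-D array")
    if np.isnan(x).any():
        raise ValueError("state coordinates contain missing values")
    return x


def distance_matrix(series, norm: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances between all state vectors of a series.

    Parameters
    ----------
    series : MultivariateSeries, DataFrame or (N, m) array
        One row per time point, one column per state variable.
    norm : {'euclidean', 'chebyshev', 'manhattan'}
    """
    if norm not in _NORMS:
        raise ValueError(
            f"unknown distance norm {norm!r}; choose one of {sorted(_NORMS)}"
        )
    x = _as_coordinates(series)
    if x.shape[0] < 2:
        raise ValueError("need at least two time points")
    D = squareform(pdist(x, metric=_NORMS[norm]))
    return DistanceMatrix(D=D, norm=norm)


def epsilon_for_target_rr(dist: DistanceMatrix, target_rr: float) -> tuple[float, float]:
    """Smallest threshold whose recurrence rate reaches ``target_rr``.

    Returns ``(epsilon, achieved_rr)`` where epsilon is the smallest observed
    pair distance d with RR(d) >= target_rr, i.e. the ceil(target * P)-th
    order statistic of the P = N(N-1)/2 pair distances.  The achieved rate
    can exceed the target when distances tie at epsilon.
    """
    if not 0 < target_rr <= 1:
        raise ValueError("target recurrence rate must lie in (0, 1]")
    pairs = np.sort(dist.condensed())
    p = pairs.size
    idx = max(0, math.ceil(target_rr * p) - 1)
    epsilon = float(pairs[idx])
    achieved = float(np.count_nonzero(pairs <= epsilon)) / p
    return epsilon, achieved


def recurrence_matrix(dist: DistanceMatrix, epsilon: float) -> RecurrenceMatrix:
    """Threshold a distance matrix into a binary recurrence matrix.

    The closed condition D_ij <= epsilon is used so that thresholds returned
    by :func:`epsilon_for_target_rr` achieve their rate exactly on ties.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    R = dist.D <= epsilon
    np.fill_diagonal(R, False)
    n = R.shape[0]
    rr = float(R.sum()) / (n * (n - 1))
    return RecurrenceMatrix(R=R, epsilon=float(epsilon), recurrence_rate=rr)


def build_crn(
    rec: RecurrenceMatrix,
    dist: DistanceMatrix | None = None,
    weight: str = "time",
    theiler: int = 0,
) -> CumulativeRN:
    """Construct the cumulative recurrence network of a recurrence matrix.

    Every recurrent pair (i, j) with j < i contributes one directed edge
    i -> j.  With ``weight='time'`` the edge weight is the recurrence time
    i - j in samples; ``weight='distance'`` keeps the phase-space distance
    instead (requires ``dist``).  ``theiler`` excludes pairs closer in time
    than the given number of samples (0 = only the diagonal is excluded).
    """
    if weight not in ("time", "distance"):
        raise ValueError("weight must be 'time' or 'distance'")
    if weight == "distance" and dist is None:
        raise ValueError("distance weights require the distance matrix")
    n = rec.n
    lower = np.tril(rec.R, k=-1)
    if theiler > 0:
        lag = np.arange(n)[:, None] - np.arange(n)[None, :]
        lower &= lag > theiler
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(lower)
    if weight == "time":
        w = (ii - jj).astype(float)
    else:
        w = dist.D[ii, jj]
    g.add_weighted_edges_from(zip(ii.tolist(), jj.tolist(), w.tolist()))
    return CumulativeRN(graph=g, epsilon=rec.epsilon, weight_kind=weight, _lower=lower)


def build_ern(rec: RecurrenceMatrix) -> nx.Graph:
    """Undirected, unweighted epsilon-recurrence network (simple graph)."""
    n = rec.n
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(rec.R, k=1))
    g.add_edges_from(zip(jj.tolist(), ii.tolist()))
    return g


def _one_based(graph):
    return nx.relabel_nodes(graph, {i: i + 1 for i in graph.nodes}, copy=True)


def write_graphml(graph, path) -> None:
    """Write a network as GraphML with 1-based time-order node labels."""
    g = graph.graph if isinstance(graph, CumulativeRN) else graph
    nx.write_graphml(_one_based(g), path)


def write_edgelist_csv(graph, path) -> None:
    """Write ``source,target,weight`` rows (1-based node labels)."""
    g = graph.graph if isinstance(graph, CumulativeRN) else graph
    with open(path, "w") as fh:
        fh.write("source,target,weight\n")
        for u, v, data in g.edges(data=True):
            fh.write(f"{u + 1},{v + 1},{data.get('weight', 1)}\n")
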