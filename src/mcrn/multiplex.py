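"""Multiplex recurrence networks and inter-layer similarity measures.

A multiplex recurrence network stacks M layer networks — one (cumulative)
recurrence network per observed subsystem — over an identical, time-aligned
node set.  Structural similarity between layers alpha and beta is measured
on node-aligned degree (or binned strength) vectors:

* inter-layer mutual information  I_ab = sum p(a,b) log[p(a,b)/(p(a)p(b))]
  over the node-wise joint frequency table, in nats;
* inter-layer Pearson correlation R_ab of the same vectors;
* edge overlap  omega = sum_i sum_{j>i} sum_a A_ij^a
                        / (M * #{(i,j): union edge present}),
  the fraction of multiplex edge slots occupied: 1 when all layers share an
  identical edge set, 1/M when layers are pairwise disjoint.

The giant NM x NM supra-adjacency matrix is never materialized; all
quantities are projections onto the M-node layer graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .measures import local_degree, local_strength
from .recurrence import CumulativeRN

__all__ = [
    "MultiplexRN",
    "InterLayerStats",
    "build_mrn",
    "interlayer_mi",
    "interlayer_correlation",
    "edge_overlap",
    "mrn_summary",
    "bin_strengths",
    "mutual_information",
    "projection_graph",
]

DEFAULT_STRENGTH_BINS = 10


@dataclass
class MultiplexRN:
    """M node-aligned layer networks plus the comparison mode."""

    layers: list
    layer_names: list[str]
    mode: str  # 'degree' | 'strength'
    n_strength_bins: int = DEFAULT_STRENGTH_BINS
    _node_vectors: np.ndarray = field(default=None, repr=False)

    @property
    def m(self) -> int:
        return len(self.layers)

    @property
    def n(self) -> int:
        return _layer_graph(self.layers[0]).number_of_nodes()


@dataclass
class InterLayerStats:
    """All pairwise inter-layer similarities of a multiplex network."""

    mi_matrix: pd.DataFrame
    corr_matrix: pd.DataFrame
    edge_overlap: float
    mean_mi: float
    mean_corr: float
    mean_strength_density: float

    def to_frame(self, label: str = "mrn") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "graph": [label],
                "mean_mi": [self.mean_mi],
                "mean_corr": [self.mean_corr],
                "edge_overlap": [self.edge_overlap],
                "mean_strength_density": [self.mean_strength_density],
            }
        )


def _layer_graph(layer):
    return layer.graph if isinstance(layer, CumulativeRN) else layer


def build_mrn(
    layers,
    mode: str = "degree",
    layer_names: list[str] | None = None,
    n_strength_bins: int = DEFAULT_STRENGTH_BINS,
) -> MultiplexRN:
    """Assemble node-aligned layer networks into a multiplex RN.

    ``mode='degree'`` compares unweighted (out-)degree sequences;
    ``mode='strength'`` compares per-layer quantile-binned (out-)strengths.
    """
    if mode not in ("degree", "strength"):
        raise ValueError("mode must be 'degree' or 'strength'")
    layers = list(layers)
    if len(layers) < 2:
        raise ValueError("a multiplex network needs at least two layers")
    names = list(layer_names) if layer_names is not None else [
        f"layer_{i + 1}" for i in range(len(layers))
    ]
    if len(names) != len(layers):
        raise ValueError("layer_names length must match the number of layers")
    sizes = [_layer_graph(l).number_of_nodes() for l in layers]
    if len(set(sizes)) != 1:
        detail = ", ".join(f"{nm}: N={sz}" for nm, sz in zip(names, sizes))
        raise ValueError(f"layers are not node-aligned ({detail})")
    return MultiplexRN(
        layers=layers, layer_names=names, mode=mode, n_strength_bins=n_strength_bins
    )


def bin_strengths(strengths: np.ndarray, n_bins: int = DEFAULT_STRENGTH_BINS) -> np.ndarray:
    """Equal-frequency (quantile) binning of a strength vector into codes.

    Bin edges are the within-layer quantiles at k/n_bins, so coarser binnings
    with n_bins' dividing n_bins are refinements merged — coarsening can only
    lose information.
    """
    s = np.asarray(strengths, dtype=float)
    edges = np.quantile(s, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, s, side="left")


def _node_vector(layer, mode: str, n_bins: int) -> np.ndarray:
    g = _layer_graph(layer)
    if mode == "degree":
        k, _ = local_degree(g, directed_mode="out" if g.is_directed() else "all")
        return k.astype(int)
    return bin_strengths(local_strength(g), n_bins)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Empirical mutual information of two aligned discrete vectors, in nats."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("vectors must be node-aligned")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx_, ny_ = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny_ + yi, minlength=nx_ * ny_).reshape(nx_, ny_)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def interlayer_mi(mrn: MultiplexRN, alpha: int, beta: int) -> float:
    """Mutual information between the degree/strength vectors of two layers.

    Returns 0 (with a warning) when either layer's vector is constant: a
    zero-entropy layer carries no structural information to share.
    """
    va = _node_vector(mrn.layers[alpha], mrn.mode, mrn.n_strength_bins)
    vb = _node_vector(mrn.layers[beta], mrn.mode, mrn.n_strength_bins)
    if np.unique(va).size < 2 or np.unique(vb).size < 2:
        warnings.warn(
            "degenerate layer with constant degree/strength vector; "
            "inter-layer mutual information is 0",
            stacklevel=2,
        )
        return 0.0
    return mutual_information(va, vb)


def interlayer_correlation(mrn: MultiplexRN, alpha: int, beta: int) -> float:
    """Pearson correlation between node-aligned degree/strength vectors."""
    va = _node_vector(mrn.layers[alpha], mrn.mode, mrn.n_strength_bins).astype(float)
    vb = _node_vector(mrn.layers[beta], mrn.mode, mrn.n_strength_bins).astype(float)
    if va.std() == 0 or vb.std() == 0:
        warnings.warn(
            "constant degree/strength vector; Pearson correlation undefined",
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


def _binary_sym_upper(layer) -> np.ndarray:
    """Condensed binary, symmetrized upper-triangle adjacency of a layer."""
    g = _layer_graph(layer)
    a = nx.to_numpy_array(g, nodelist=sorted(g.nodes), weight=None).astype(bool)
    a |= a.T
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def edge_overlap(mrn: MultiplexRN) -> float:
    """Fraction of multiplex edge slots occupied across all layers.

    Directed layers are symmetrized (the sum runs over unordered pairs) and
    weights are ignored.
    """
    slots = np.stack([_binary_sym_upper(l) for l in mrn.layers])
    counts = slots.sum(axis=0)
    union = int(np.count_nonzero(counts))
    if union == 0:
        raise ValueError("edge overlap undefined: no layer has any edge")
    return float(counts.sum()) / (mrn.m * union)


def _strength_density(layer) -> float:
    g = _layer_graph(layer)
    n = g.number_of_nodes()
    return float(local_strength(g).mean() / (n - 1))


def mrn_summary(mrn: MultiplexRN) -> InterLayerStats:
    """All pairwise inter-layer similarities plus their off-diagonal means."""
    m = mrn.m
    mi = np.zeros((m, m))
    rr = np.eye(m)
    for a in range(m):
        mi[a, a] = interlayer_mi(mrn, a, a)
        for b in range(a + 1, m):
            mi[a, b] = mi[b, a] = interlayer_mi(mrn, a, b)
            rr[a, b] = rr[b, a] = interlayer_correlation(mrn, a, b)
    off = ~np.eye(m, dtype=bool)
    names = mrn.layer_names
    return InterLayerStats(
        mi_matrix=pd.DataFrame(mi, index=names, columns=names),
        corr_matrix=pd.DataFrame(rr, index=names, columns=names),
        edge_overlap=edge_overlap(mrn),
        mean_mi=float(mi[off].mean()),
        mean_corr=float(np.nanmean(rr[off])) if np.isfinite(rr[off]).any() else float("nan"),
        mean_strength_density=float(np.mean([_strength_density(l) for l in mrn.layers])),
    )


def projection_graph(mrn: MultiplexRN, stats: InterLayerStats | None = None) -> nx.Graph:
    """M-node projection with MI and overlap attributes on the edges."""
    stats = stats if stats is not None else mrn_summary(mrn)
    g = nx.Graph()
    g.add_nodes_from(mrn.layer_names)
    for i, a in enumerate(mrn.layer_names):
        for j in range(i + 1, mrn.m):
            b = mrn.layer_names[j]
            g.add_edge(
                a,
                b,
                mutual_information=float(stats.mi_matrix.loc[a, b]),
                correlation=float(stats.corr_matrix.loc[a, b]),
            )
    g.graph["edge_overlap"] = stats.edge_overlap
    return g
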