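"""Recurring phase profiles and phase-transition networks.

Recurrent regions of phase space are treated as discrete states: connected
components of the undirected epsilon-recurrence network with at least
``min_size`` member time points become phases, characterized by the
per-variable median of their member coordinates and numbered from most to
least frequently recurring.  Time points in smaller components form a
residual singleton class, so every time point carries exactly one label and
the sequence of labels supports an empirical, row-stochastic transition
matrix and its directed transition network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .prep import MultivariateSeries
from .recurrence import RecurrenceMatrix

__all__ = [
    "PhaseAssignment",
    "TransitionMatrix",
    "RESIDUAL",
    "extract_phases",
    "transition_matrix",
    "transition_network",
]

RESIDUAL = 0  # label of the residual / singleton class


@dataclass
class PhaseAssignment:
    """Phase label per time point plus phase profiles and frequencies.

    Labels 1..n_phases are ordered by descending frequency (ties broken by
    earliest member time index); label 0 marks the residual class.
    """

    labels: np.ndarray
    n_phases: int
    profiles: pd.DataFrame  # one row per phase, one column per variable
    frequencies: pd.Series  # phase id -> member count (residual included)

    def __post_init__(self):
        if int(self.frequencies.sum()) != self.labels.size:
            raise ValueError("phase frequencies must sum to the series length")


@dataclass
class TransitionMatrix:
    P: pd.DataFrame       # row-stochastic where the row has outgoing counts
    counts: pd.DataFrame  # raw consecutive-pair tallies


def extract_phases(
    rec: RecurrenceMatrix, series, min_size: int = 2
) -> PhaseAssignment:
    """Group time points into recurring phases.

    Connected components of the undirected eps-RN with >= ``min_size``
    members become phases; their profile is the per-variable median of the
    member state vectors.  Everything else is residual.
    """
    if isinstance(series, MultivariateSeries):
        frame = series.values
    else:
        arr = np.asarray(getattr(series, "values", series), dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        frame = pd.DataFrame(arr)
    n = rec.n
    if len(frame) != n:
        raise ValueError("recurrence matrix and series are not aligned")
    _, comp = connected_components(csr_matrix(rec.R), directed=False)
    groups = []
    for cid in np.unique(comp):
        members = np.nonzero(comp == cid)[0]
        if members.size >= min_size:
            groups.append(members)
    groups.sort(key=lambda mem: (-mem.size, mem.min()))
    labels = np.full(n, RESIDUAL, dtype=int)
    profiles = {}
    freqs = {}
    for rank, members in enumerate(groups, start=1):
        labels[members] = rank
        profiles[rank] = frame.iloc[members].median()
        freqs[rank] = int(members.size)
    n_res = int((labels == RESIDUAL).sum())
    if n_res:
        freqs[RESIDUAL] = n_res
    prof = (
        pd.DataFrame(profiles).T.rename_axis("phase")
        if profiles
        else pd.DataFrame(columns=frame.columns).rename_axis("phase")
    )
    return PhaseAssignment(
        labels=labels,
        n_phases=len(groups),
        profiles=prof,
        frequencies=pd.Series(freqs, dtype=int).sort_index(),
    )


def transition_matrix(
    assignment: PhaseAssignment, include_residual: bool = True
) -> TransitionMatrix:
    """Empirical first-order transition matrix of the phase label sequence.

    With ``include_residual`` off, the residual row and column are dropped
    from the counts before renormalizing (marginalization).
    """
    labels = assignment.labels
    if labels.size < 2:
        raise ValueError("need at least two time points")
    ids = sorted(set(labels.tolist()))
    index = {lab: i for i, lab in enumerate(ids)}
    k = len(ids)
    counts = np.zeros((k, k), dtype=int)
    for a, b in zip(labels[:-1], labels[1:]):
        counts[index[a], index[b]] += 1
    names = [("residual" if lab == RESIDUAL else f"phase_{lab}") for lab in ids]
    cdf = pd.DataFrame(counts, index=names, columns=names)
    if not include_residual and RESIDUAL in index:
        cdf = cdf.drop(index="residual", columns="residual")
    totals = cdf.sum(axis=1)
    P = cdf.div(totals.where(totals > 0, 1), axis=0).astype(float)
    return TransitionMatrix(P=P, counts=cdf)


def transition_network(tm: TransitionMatrix, display_min: float = 0.10) -> nx.DiGraph:
    """Directed graph with an edge a -> b iff P_ab >= display_min.

    Self-loops are retained; edge weights are the transition probabilities.
    """
    g = nx.DiGraph()
    g.add_nodes_from(tm.P.index)
    for a in tm.P.index:
        for b in tm.P.columns:
            p = float(tm.P.loc[a, b])
            if p > 0 and p >= display_min:
                g.add_edge(a, b, weight=p)
    return g
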