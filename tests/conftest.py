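import numpy as np
import pandas as pd
import pytest

from mcrn import prep, recurrence


@pytest.fixture
def toy_series():
    """1-D series whose recurrence structure is enumerable by hand."""
    return np.array([1.0, 2.0, 1.05, 3.0, 1.0])


@pytest.fixture
def toy_recurrence(toy_series):
    """Recurrence matrix of the toy series at epsilon = 0.1 (RR = 0.3)."""
    d = recurrence.distance_matrix(toy_series)
    return recurrence.recurrence_matrix(d, 0.1)


@pytest.fixture
def raw_table():
    """Small two-variable raw table with one missing cell."""
    idx = pd.date_range("2021-01-01", periods=20, freq="D")
    rng = np.random.default_rng(42)
    a = rng.normal(4, 1, size=20)
    frame = pd.DataFrame({"a": a, "b": a * 0.8 + rng.normal(0, 0.2, size=20)}, index=idx)
    frame.iloc[5, 1] = np.nan
    return prep.RawTable(
        frame=frame,
        subsystem_map={"a": "s1", "b": "s1"},
        scale_range=(0.0, 8.0),
    )


def random_graph(rng, n=None, p=None, directed=False):
    """Erdos-Renyi graph helper used by the oracle tests."""
    import networkx as nx

    n = n if n is not None else int(rng.integers(4, 31))
    p = p if p is not None else float(rng.uniform(0.05, 0.6))
    seed = int(rng.integers(0, 2**31 - 1))
    return nx.gnp_random_graph(n, p, seed=seed, directed=directed)
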