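"""Sliding-window multiplex indicators, surrogate bands and peak flags.

For every right-aligned window of ``window`` days the subsystem series are
turned into per-window cumulative recurrence networks (threshold re-derived
inside the window to hit a fixed recurrence-rate target, so the indicators
track geometry rather than density drift), assembled into a multiplex
network, and summarized by three layer-similarity measures:

* ``edge_overlap`` — fraction of multiplex edge slots occupied,
* ``mean_mi``      — mean strength-based inter-layer mutual information,
* ``mean_corr``    — mean Pearson correlation of out-strength vectors.

Rising values signal that the subsystems' phase-space layers are becoming
structurally more similar — the geometric resilience-loss signature that
precedes critical transitions.  A windowed variance / lag-1 autocorrelation
trace is provided as the classical critical-slowing-down baseline.

Reference bands come from surrogate series (row shuffles or block
permutations of the original rows); a day is flagged when an indicator
strictly exceeds the band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multiplex import bin_strengths, mutual_information
from .prep import MultivariateSeries

__all__ = [
    "IndicatorTrace",
    "SurrogateBand",
    "Flag",
    "MEASURES",
    "split_subsystems",
    "windowed_mrn_trace",
    "unit_scale",
    "windowed_var_acf",
    "surrogate_band",
    "flag_peaks",
    "segment_analysis",
]

MEASURES = ("edge_overlap", "mean_mi", "mean_corr")


@dataclass
class IndicatorTrace:
    """Right-aligned windowed indicator values.

    ``values`` is indexed by the window-end day (0-based); row t summarizes
    days t-window+1 .. t, so the trace has N - window + 1 rows.
    """

    values: pd.DataFrame
    window: int
    unit_scaled: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def time_index(self) -> np.ndarray:
        return self.values.index.to_numpy()


@dataclass
class SurrogateBand:
    """Per-time upper reference quantile computed from surrogate traces."""

    band: pd.DataFrame
    n_surrogates: int
    method: str
    block_length: int | None
    quantile: float
    seed: int


@dataclass
class Flag:
    day: int
    measure: str
    value: float
    band_value: float
    pre_event: bool = False
    event_day: int | None = None


def split_subsystems(series: MultivariateSeries) -> dict[str, np.ndarray]:
    """Per-subsystem coordinate arrays sharing the series' time index."""
    return {name: block.to_numpy(dtype=float) for name, block in series.subsystems().items()}


def _coerce_layers(series_by_subsystem) -> dict[str, np.ndarray]:
    if isinstance(series_by_subsystem, MultivariateSeries):
        return split_subsystems(series_by_subsystem)
    out = {}
    for name, block in series_by_subsystem.items():
        if isinstance(block, MultivariateSeries):
            arr = block.values.to_numpy(dtype=float)
        else:
            arr = np.asarray(getattr(block, "values", block), dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        out[name] = arr
    lengths = {a.shape[0] for a in out.values()}
    if len(lengths) != 1:
        raise ValueError("subsystem series must share the time index")
    return out


class _WindowKernel:
    """Per-window cRN construction on raw arrays (no graph objects).

    Out-degree/out-strength of node i in a window count recurrent pairs
    (i, j) with j < i and their recurrence times i - j — identical to
    building the cumulative network and reading vertex measures, but cheap
    enough for tens of thousands of windows.
    """

    def __init__(self, window: int):
        self.w = window
        self.ii, self.jj = np.triu_indices(window, k=1)  # jj later than ii
        self.lag = (self.jj - self.ii).astype(float)
        self.n_pairs = self.ii.size

    def layer(self, x: np.ndarray, rr_target: float | None, epsilon: float | None):
        """Condensed recurrence mask, out-degrees, out-strengths, epsilon."""
        diff = x[self.jj] - x[self.ii]
        d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        if epsilon is None:
            order = np.sort(d)
            idx = max(0, int(np.ceil(rr_target * self.n_pairs)) - 1)
            epsilon = order[idx]
        mask = d <= epsilon
        out_deg = np.bincount(self.jj[mask], minlength=self.w)
        out_str = np.bincount(self.jj[mask], weights=self.lag[mask], minlength=self.w)
        return mask, out_deg, out_str, float(epsilon)


def _pairwise_measures(masks, strengths, m_layers, n_bins):
    """Edge overlap, mean strength-MI and mean strength-correlation."""
    counts = masks.sum(axis=0)
    union = int(np.count_nonzero(counts))
    overlap = counts.sum() / (m_layers * union) if union else np.nan
    codes = [bin_strengths(s, n_bins) for s in strengths]
    mis, corrs = [], []
    for a in range(m_layers):
        for b in range(a + 1, m_layers):
            ca, cb = codes[a], codes[b]
            if np.unique(ca).size < 2 or np.unique(cb).size < 2:
                mis.append(0.0)
            else:
                mis.append(mutual_information(ca, cb))
            sa, sb = strengths[a], strengths[b]
            if sa.std() == 0 or sb.std() == 0:
                corrs.append(np.nan)
            else:
                corrs.append(float(np.corrcoef(sa, sb)[0, 1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_corr = float(np.nanmean(corrs)) if corrs else np.nan
    return float(overlap), float(np.mean(mis)), mean_corr


def windowed_mrn_trace(
    series_by_subsystem,
    window: int = 7,
    rr_target: float = 0.05,
    epsilon_map: dict | None = None,
    n_strength_bins: int = 10,
    min_distinct: int = 3,
) -> IndicatorTrace:
    """Sliding-window multiplex cRN similarity trace.

    Thresholds are re-derived per window and per subsystem from
    ``rr_target`` unless a fixed ``epsilon_map`` (subsystem -> epsilon) is
    given.  Windows in which any subsystem shows fewer than ``min_distinct``
    distinct state vectors yield missing values.
    """
    layers = _coerce_layers(series_by_subsystem)
    names = list(layers)
    m = len(names)
    if m < 2:
        raise ValueError("need at least two subsystems for a multiplex trace")
    n = next(iter(layers.values())).shape[0]
    if window < 3:
        raise ValueError("window must span at least 3 days")
    if window > n:
        raise ValueError(f"window ({window}) longer than the series ({n})")
    kernel = _WindowKernel(window)
    ends = np.arange(window - 1, n)
    rows = np.full((ends.size, len(MEASURES)), np.nan)
    eps_log = {name: [] for name in names}
    for r, t in enumerate(ends):
        sl = slice(t - window + 1, t + 1)
        masks = np.empty((m, kernel.n_pairs), dtype=bool)
        strengths = []
        degenerate = False
        for li, name in enumerate(names):
            x = layers[name][sl]
            if np.unique(x, axis=0).shape[0] < min_distinct:
                degenerate = True
                break
            eps = None if epsilon_map is None else epsilon_map[name]
            mask, _, out_str, eps_used = kernel.layer(
                x, rr_target if epsilon_map is None else None, eps
            )
            masks[li] = mask
            strengths.append(out_str)
            eps_log[name].append(eps_used)
        if degenerate:
            continue
        rows[r] = _pairwise_measures(masks, strengths, m, n_strength_bins)
    values = pd.DataFrame(rows, index=pd.Index(ends, name="day"), columns=list(MEASURES))
    meta = {
        "window": window,
        "rr_target": None if epsilon_map is not None else rr_target,
        "epsilon_map": epsilon_map,
        "epsilon_range": {
            name: (float(np.min(v)), float(np.max(v))) if v else None
            for name, v in eps_log.items()
        },
        "subsystems": names,
    }
    return IndicatorTrace(values=values, window=window, meta=meta)


def unit_scale(trace: IndicatorTrace, reference="full") -> IndicatorTrace:
    """Min-max transform each measure to the unit scale.

    ``reference='full'`` uses the whole trace; a ``(start, end)`` day pair
    restricts the min/max to that segment, in which case values outside it
    may leave [0, 1].  Constant measures map to 0 with a warning.
    """
    vals = trace.values
    if reference == "full":
        ref = vals
    else:
        start, end = reference
        ref = vals.loc[(vals.index >= start) & (vals.index <= end)]
        if ref.empty:
            raise ValueError("reference segment contains no trace points")
    lo, hi = ref.min(), ref.max()
    out = vals.copy()
    for col in vals.columns:
        span = hi[col] - lo[col]
        if not np.isfinite(span) or span == 0:
            warnings.warn(f"constant measure {col!r}; unit scale maps it to 0", stacklevel=2)
            out[col] = np.where(vals[col].notna(), 0.0, np.nan)
        else:
            out[col] = (vals[col] - lo[col]) / span
    return IndicatorTrace(
        values=out, window=trace.window, unit_scaled=True,
        meta={**trace.meta, "unit_scale_reference": reference},
    )


def _lag1_autocorr(x: np.ndarray) -> float:
    a, b = x[:-1], x[1:]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def windowed_var_acf(
    series, window: int = 30, aggregate: str = "mean"
) -> IndicatorTrace:
    """Windowed sample variance and lag-1 autocorrelation (the classical
    critical-slowing-down indicators), right-aligned.

    ``aggregate='mean'`` first averages the variables into one series;
    ``'per-variable'`` emits ``<var>:variance`` / ``<var>:acf1`` columns.
    Zero-variance windows yield a missing autocorrelation.
    """
    if isinstance(series, MultivariateSeries):
        frame = series.values
    elif isinstance(series, pd.DataFrame):
        frame = series.astype(float)
    else:
        frame = pd.DataFrame(np.asarray(series, dtype=float))
    n = len(frame)
    if window < 3:
        raise ValueError("window must span at least 3 days")
    if window > n:
        raise ValueError(f"window ({window}) longer than the series ({n})")
    if aggregate == "mean":
        data = {"state": frame.mean(axis=1).to_numpy()}
    elif aggregate == "per-variable":
        data = {str(c): frame[c].to_numpy() for c in frame.columns}
    else:
        raise ValueError("aggregate must be 'mean' or 'per-variable'")
    ends = np.arange(window - 1, n)
    cols = {}
    for name, x in data.items():
        var = np.empty(ends.size)
        acf = np.empty(ends.size)
        for r, t in enumerate(ends):
            w = x[t - window + 1 : t + 1]
            var[r] = w.var(ddof=1)
            acf[r] = _lag1_autocorr(w) if var[r] > 0 else np.nan
        prefix = "" if (aggregate == "mean") else f"{name}:"
        cols[f"{prefix}variance"] = var
        cols[f"{prefix}acf1"] = acf
    values = pd.DataFrame(cols, index=pd.Index(ends, name="day"))
    return IndicatorTrace(values=values, window=window, meta={"aggregate": aggregate})


def _permuted_rows(n: int, method: str, block_length: int | None, rng) -> np.ndarray:
    if method == "shuffle":
        return rng.permutation(n)
    if method == "block":
        if block_length is None or block_length < 1:
            raise ValueError("block method needs a positive block_length")
        if block_length >= n:
            raise ValueError("block_length must be smaller than the series length")
        starts = np.arange(0, n, block_length)
        order = rng.permutation(starts.size)
        return np.concatenate(
            [np.arange(starts[b], min(starts[b] + block_length, n)) for b in order]
        )
    raise ValueError("method must be 'shuffle' or 'block'")


def surrogate_band(
    series_by_subsystem,
    window: int = 7,
    n_surrogates: int = 19,
    method: str = "shuffle",
    block_length: int | None = 7,
    quantile: float = 0.95,
    seed: int = 0,
    rr_target: float = 0.05,
    epsilon_map: dict | None = None,
) -> SurrogateBand:
    """Upper reference band from row-permutation surrogates.

    Every surrogate applies one joint row permutation to all subsystems
    (preserving the cross-sectional structure), recomputes the full
    indicator trace, and the band is the per-time ``quantile`` order
    statistic (index ceil(q * n) - 1 of the sorted surrogate values); with
    19 surrogates at the 0.95 quantile this is the per-time maximum.
    """
    if n_surrogates < int(np.ceil(1.0 / (1.0 - quantile))) - 1:
        raise ValueError(
            f"{n_surrogates} surrogates cannot support the {quantile} quantile"
        )
    layers = _coerce_layers(series_by_subsystem)
    n = next(iter(layers.values())).shape[0]
    rng = np.random.default_rng(seed)
    stack = []
    for _ in range(n_surrogates):
        child = np.random.default_rng(rng.integers(0, 2**31 - 1))
        perm = _permuted_rows(n, method, block_length, child)
        permuted = {name: arr[perm] for name, arr in layers.items()}
        tr = windowed_mrn_trace(
            permuted, window=window, rr_target=rr_target, epsilon_map=epsilon_map
        )
        stack.append(tr.values.to_numpy())
    cube = np.stack(stack)  # (surrogates, time, measures)
    order = np.sort(cube, axis=0)
    idx = int(np.ceil(quantile * n_surrogates)) - 1
    template = windowed_mrn_trace(
        layers, window=window, rr_target=rr_target, epsilon_map=epsilon_map
    ).values
    band = pd.DataFrame(order[idx], index=template.index, columns=template.columns)
    return SurrogateBand(
        band=band,
        n_surrogates=n_surrogates,
        method=method,
        block_length=block_length if method == "block" else None,
        quantile=quantile,
        seed=seed,
    )


def flag_peaks(
    trace: IndicatorTrace,
    band: SurrogateBand,
    events=None,
    lead_window: int = 14,
    measures=None,
) -> list[Flag]:
    """Days on which an indicator strictly exceeds the surrogate band.

    ``events`` is an iterable of event days (or a DataFrame with a ``day``
    column); a flag falling within ``lead_window`` days before an event is
    annotated as pre-event.
    """
    vals = trace.values
    bnd = band.band
    if not vals.index.equals(bnd.index):
        raise ValueError("trace and band are not aligned")
    if events is None:
        event_days = []
    elif hasattr(events, "columns"):
        event_days = list(events["day"])
    else:
        event_days = list(events)
    flags = []
    cols = measures if measures is not None else vals.columns
    for col in cols:
        v = vals[col]
        b = bnd[col]
        hit = (v > b) & v.notna() & b.notna()
        for day in vals.index[hit]:
            pre = [e for e in event_days if 0 < e - day <= lead_window]
            flags.append(
                Flag(
                    day=int(day),
                    measure=str(col),
                    value=float(v.loc[day]),
                    band_value=float(b.loc[day]),
                    pre_event=bool(pre),
                    event_day=int(min(pre)) if pre else None,
                )
            )
    return sorted(flags, key=lambda f: (f.day, f.measure))


def segment_analysis(
    series_by_subsystem,
    segments,
    rr_target: float = 0.05,
    n_strength_bins: int = 10,
) -> pd.DataFrame:
    """Whole-segment multiplex cRN summaries, one row per segment.

    ``segments`` is an iterable of ``(start, end, label)`` with end
    exclusive.  This is a post-hoc comparison — it requires the whole
    segment to have been observed — offered to contrast data-segmentation
    with the windowed, real-time indicators.
    """
    layers = _coerce_layers(series_by_subsystem)
    names = list(layers)
    n = next(iter(layers.values())).shape[0]
    rows = []
    for start, end, label in segments:
        if not (0 <= start < end <= n):
            raise ValueError(f"segment {label!r} [{start}, {end}) outside the series")
        length = end - start
        if length < 3:
            raise ValueError(f"segment {label!r} shorter than 3 days")
        kernel = _WindowKernel(length)
        masks = np.empty((len(names), kernel.n_pairs), dtype=bool)
        strengths = []
        for li, name in enumerate(names):
            mask, _, out_str, _ = kernel.layer(layers[name][start:end], rr_target, None)
            masks[li] = mask
            strengths.append(out_str)
        overlap, mean_mi, mean_corr = _pairwise_measures(
            masks, strengths, len(names), n_strength_bins
        )
        rows.append(
            {
                "label": label, "start": start, "end": end, "n_days": length,
                "edge_overlap": overlap, "mean_mi": mean_mi, "mean_corr": mean_corr,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["post_hoc"] = True
    return out
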