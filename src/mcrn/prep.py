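"""Loading, filtering, rescaling, aggregation and imputation of raw series.

Raw experience-sampling or sensor tables arrive as wide CSV (one row per
observation, one column per variable, plus a timestamp column), with
variables grouped into conceptual subsystems.  The preparation pipeline is

    load -> select variables -> aggregate to 1/day -> rescale & recode
         -> impute missing cells,

yielding a complete daily-resolution matrix on a common bounded scale.

Variable selection applies a support criterion: a variable is kept when its
missing fraction is below ``max_missing`` (default 5%) and the fraction of
zeros in its first-differenced series — a proxy for sufficient dynamics —
is below ``max_diff_zeros`` (default 33%); variables of declared theoretical
relevance can be exempted.  Missing cells are imputed by seeded chained
regression (scikit-learn's iterative imputer), restricted to variables of
the same subsystem so each subsystem's phase space is completed from its
own dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

__all__ = [
    "RawTable",
    "MultivariateSeries",
    "SelectionResult",
    "load_wide_csv",
    "load_config",
    "select_variables",
    "aggregate_daily",
    "rescale_and_recode",
    "impute_missing",
]

DEFAULT_MISSING_CODES = ("", "NA", "NaN")


@dataclass
class RawTable:
    """Wide observation table with subsystem and recoding metadata.

    ``frame`` holds one row per observation with a DatetimeIndex (sorted,
    non-decreasing) and one float column per variable (NaN = missing).
    """

    frame: pd.DataFrame
    reverse_coded: frozenset = frozenset()
    subsystem_map: dict = field(default_factory=dict)
    scale_range: tuple | None = None

    def __post_init__(self):
        if not self.frame.index.is_monotonic_increasing:
            raise ValueError("timestamps must be non-decreasing")
        unknown = set(self.subsystem_map) - set(self.frame.columns)
        if unknown:
            raise ValueError(
                f"subsystem_map names variables absent from the table: {sorted(unknown)}"
            )
        self.reverse_coded = frozenset(self.reverse_coded)

    @property
    def variable_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_rows(self) -> int:
        return len(self.frame)


@dataclass
class MultivariateSeries:
    """Complete daily-resolution state matrix: N days x m variables.

    Rows are state vectors y_i of the (sub)system phase space, indexed by a
    consecutive integer day index; calendar dates are kept alongside when
    known.
    """

    values: pd.DataFrame  # integer day index, float values, no NaN
    scale_range: tuple
    subsystem_map: dict = field(default_factory=dict)
    dates: pd.DatetimeIndex | None = None

    def __post_init__(self):
        v = self.values
        if v.isna().any().any():
            raise ValueError("a MultivariateSeries must have no missing values")
        if len(v) < 2 or v.shape[1] < 1:
            raise ValueError("need at least 2 time points and 1 variable")
        lo, hi = self.scale_range
        arr = v.to_numpy()
        if arr.min() < lo - 1e-9 or arr.max() > hi + 1e-9:
            raise ValueError("values fall outside the declared scale range")
        self.values = v.set_axis(pd.RangeIndex(len(v)), axis=0)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def subsystems(self) -> dict[str, pd.DataFrame]:
        """Column blocks per subsystem label, in first-appearance order."""
        if not self.subsystem_map:
            return {"all": self.values}
        order: dict[str, list[str]] = {}
        for var in self.values.columns:
            label = self.subsystem_map.get(var, "other")
            order.setdefault(label, []).append(var)
        return {label: self.values[cols] for label, cols in order.items()}


class SelectionResult(NamedTuple):
    table: RawTable
    report: pd.DataFrame  # variable, kept, reason, missing_frac, diff_zero_frac


def load_wide_csv(
    path,
    timestamp_column: str,
    missing_codes=DEFAULT_MISSING_CODES,
    reverse_coded=(),
    subsystem_map: dict | None = None,
    delimiter: str = ",",
) -> RawTable:
    """Read a wide-format delimited table into a :class:`RawTable`.

    Cells equal to one of ``missing_codes`` become missing; any other
    non-numeric cell is an error naming the offending rows.  Rows are
    returned sorted by timestamp.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=delimiter)
    if timestamp_column not in df.columns:
        raise ValueError(
            f"timestamp column {timestamp_column!r} not found in {list(df.columns)}"
        )
    ts = pd.to_datetime(df[timestamp_column], format="mixed")
    values = df.drop(columns=[timestamp_column])
    values = values.apply(lambda c: c.str.strip())
    missing = values.isin(set(missing_codes))
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~missing
    if bad.any().any():
        rows = sorted(set((np.nonzero(bad.to_numpy())[0] + 2).tolist()))  # 1-based + header
        raise ValueError(f"non-numeric cells outside declared missing codes in rows {rows}")
    numeric[missing] = np.nan
    numeric.index = pd.DatetimeIndex(ts)
    numeric = numeric.sort_index(kind="stable")
    return RawTable(
        frame=numeric,
        reverse_coded=frozenset(reverse_coded),
        subsystem_map=dict(subsystem_map or {}),
    )


def load_config(path) -> dict:
    """Read a YAML run configuration.

    Recognized keys: ``subsystems`` (subsystem -> list of variables),
    ``reverse_coded``, ``exempt``, ``thresholds`` (max_missing,
    max_diff_zeros, rr_target), ``scale`` ([lo, hi]), ``window``,
    ``surrogates`` and ``seed``.  A flat ``variable -> subsystem`` map is
    derived under ``subsystem_map``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    subsystems = cfg.get("subsystems", {})
    cfg["subsystem_map"] = {
        var: label for label, cols in subsystems.items() for var in cols
    }
    return cfg


def _missing_fraction(col: pd.Series) -> float:
    return float(col.isna().mean())


def _diff_zero_fraction(col: pd.Series) -> float:
    d = col.dropna().diff().dropna()
    if d.empty:
        return 1.0  # no observable dynamics
    return float((d == 0).mean())


def select_variables(
    raw: RawTable,
    max_missing: float = 0.05,
    max_diff_zeros: float = 0.33,
    exempt=(),
) -> SelectionResult:
    """Apply the support criterion to each variable.

    A variable is kept iff (missing fraction < max_missing AND zero fraction
    of its first-differenced series < max_diff_zeros) or it is exempt.  Both
    inequalities are strict.  The report lists every variable with the
    reason for exclusion.
    """
    if not (0 <= max_missing <= 1 and 0 <= max_diff_zeros <= 1):
        raise ValueError("thresholds must be proportions in [0, 1]")
    exempt = set(exempt)
    rows = []
    kept = []
    for var in raw.variable_names:
        col = raw.frame[var]
        mf = _missing_fraction(col)
        zf = _diff_zero_fraction(col)
        if var in exempt:
            keep, reason = True, "exempt"
        elif mf >= max_missing:
            keep, reason = False, f"missing fraction {mf:.3f} >= {max_missing}"
        elif zf >= max_diff_zeros:
            keep, reason = False, f"differenced-series zero fraction {zf:.3f} >= {max_diff_zeros}"
        else:
            keep, reason = True, "passed support criterion"
        if keep:
            kept.append(var)
        rows.append(
            {"variable": var, "kept": keep, "reason": reason,
             "missing_frac": mf, "diff_zero_frac": zf}
        )
    if not kept:
        raise ValueError("variable selection excluded every variable")
    table = replace(
        raw,
        frame=raw.frame[kept],
        reverse_coded=frozenset(v for v in raw.reverse_coded if v in kept),
        subsystem_map={v: s for v, s in raw.subsystem_map.items() if v in kept},
    )
    return SelectionResult(table=table, report=pd.DataFrame(rows))


def aggregate_daily(raw: RawTable) -> RawTable:
    """Aggregate to one row per calendar day (arithmetic mean of the day's
    non-missing observations; a day without observations stays missing).

    The output covers every calendar day between the first and last
    timestamp, so the daily index is consecutive.
    """
    daily = raw.frame.groupby(raw.frame.index.normalize()).mean()
    full = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
    daily = daily.reindex(full)
    return replace(raw, frame=daily)


def rescale_and_recode(raw: RawTable, lo: float = 1.0, hi: float = 7.0) -> RawTable:
    """Affinely map each variable's observed range onto [lo, hi], then
    reflect reverse-coded variables (v -> lo + hi - v).

    Variables with a constant observed value map to the midpoint.
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    out = raw.frame.copy()
    for var in out.columns:
        col = out[var]
        vmin, vmax = col.min(), col.max()
        if pd.isna(vmin) or vmax == vmin:
            out[var] = col.where(col.isna(), (lo + hi) / 2.0)
        else:
            out[var] = lo + (col - vmin) / (vmax - vmin) * (hi - lo)
        if var in raw.reverse_coded:
            out[var] = lo + hi - out[var]
    return replace(raw, frame=out, scale_range=(lo, hi))


def impute_missing(
    raw: RawTable,
    seed: int = 0,
    per_subsystem: bool = True,
    max_iter: int = 10,
    tol: float = 1e-3,
) -> MultivariateSeries:
    """Complete the table by seeded chained-regression imputation.

    Each variable with missing cells is regressed round-robin on the other
    variables of the same subsystem (or of the whole table when
    ``per_subsystem`` is off), for up to ``max_iter`` sweeps or until the
    largest imputed-cell change drops below ``tol``.  Imputed values are
    clipped to the scale range.  Identical seed, identical output.
    """
    frame = raw.frame
    starved = [v for v in frame.columns if frame[v].notna().sum() < 2]
    if starved:
        raise ValueError(
            f"cannot impute: variable(s) with fewer than two observed values: {starved}"
        )
    if raw.scale_range is not None:
        lo, hi = raw.scale_range
    else:
        lo, hi = float(np.nanmin(frame.to_numpy())), float(np.nanmax(frame.to_numpy()))
    if per_subsystem and raw.subsystem_map:
        groups: dict[str, list[str]] = {}
        for var in frame.columns:
            groups.setdefault(raw.subsystem_map.get(var, "other"), []).append(var)
        blocks = list(groups.values())
    else:
        blocks = [list(frame.columns)]
    out = frame.copy()
    for cols in blocks:
        block = frame[cols]
        if block.isna().any().any():
            imputer = IterativeImputer(
                max_iter=max_iter,
                tol=tol,
                random_state=seed,
                sample_posterior=False,
                min_value=lo,
                max_value=hi,
            )
            out[cols] = imputer.fit_transform(block.to_numpy())
    dates = out.index if isinstance(out.index, pd.DatetimeIndex) else None
    return MultivariateSeries(
        values=out,
        scale_range=(lo, hi),
        subsystem_map=dict(raw.subsystem_map),
        dates=dates,
    )
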