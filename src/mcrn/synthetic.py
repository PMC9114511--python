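"""Seeded generators of ordinal multivariate series with a regime shift.

The regime-shift generator emulates the shape of long experience-sampling
records: several subsystems of bounded 1..L ordinal self-ratings observed
daily over ~200+ days, with injected missingness and reverse-scored items.
Latent dynamics are a stationary AR(1) per variable plus a shared AR(1)
common factor.  Over the 14 days before a known shift day the system
approaches a tipping point of its shared mode: the factor's loading and
innovation gain ramp up (rising coupling and critical fluctuations) and its
autoregressive coefficient ramps toward 1 (critical slowing down), after
which the level shifts.  The increasingly dominant slow common mode makes
the subsystems' phase-space trajectories coherent just before the
transition — the geometric early-warning phenomenon the monitoring pipeline
is designed to detect — without claiming to model any particular disorder.

A weekly scalar "state variable" with a step at the first week boundary at
or after the shift is generated alongside, standing in for an infrequently
administered symptom scale against which daily indicators are judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .prep import RawTable

__all__ = ["SyntheticSpec", "gen_regime_shift_series", "gen_weekly_state_variable", "gen_iid_null"]


def _default_subsystems() -> dict[str, int]:
    return {"mood": 6, "physical": 4, "selfesteem": 3, "patience": 4, "sleep": 4, "day": 4}


@dataclass
class SyntheticSpec:
    """Parameters of the regime-shift generator.

    coupling_pre/coupling_post are the common-factor loadings before the
    ramp and at/after the shift; noise_sd is the innovation scale of the
    per-variable AR(1); ordinal_levels bounds the observed rating scale.
    """

    n_days: int = 238
    subsystems: dict = field(default_factory=_default_subsystems)
    shift_day: int = 127
    ramp_days: int = 14
    coupling_pre: float = 0.1
    coupling_post: float = 2.0
    noise_sd: float = 1.3
    ar: float = 0.3
    factor_ar: float = 0.6
    factor_ar_critical: float = 0.95
    noise_gain_post: float = 2.0
    projection_gain: float = 1.6
    level_shift: float = 2.0  # in observed scale levels
    ordinal_levels: int = 7
    missing_rate: float = 0.02
    reverse_coded_fraction: float = 0.25
    missing_block: tuple | None = None  # (start_day, end_day) of halted measurement
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.shift_day < self.n_days:
            raise ValueError("shift_day must fall strictly inside the series")
        if not 0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")
        if self.ordinal_levels < 2:
            raise ValueError("need at least two ordinal levels")
        if not self.subsystems:
            raise ValueError("at least one subsystem is required")


def coupling_schedule(spec: SyntheticSpec) -> np.ndarray:
    """Common-factor loading per day: triangular around the shift.

    The loading rises linearly from coupling_pre to coupling_post over the
    ``ramp_days`` before the shift (the approach to the tipping point) and
    relaxes back over the ``ramp_days`` after it (the new regime is stable
    again); elsewhere it is flat at coupling_pre.
    """
    lam = np.full(spec.n_days, spec.coupling_pre, dtype=float)
    start = max(0, spec.shift_day - spec.ramp_days)
    up = np.linspace(spec.coupling_pre, spec.coupling_post, spec.shift_day - start + 1)
    lam[start : spec.shift_day + 1] = up
    end = min(spec.n_days - 1, spec.shift_day + spec.ramp_days)
    down = np.linspace(spec.coupling_post, spec.coupling_pre, end - spec.shift_day + 1)
    lam[spec.shift_day : end + 1] = down
    return lam


def gen_regime_shift_series(spec: SyntheticSpec) -> tuple[RawTable, dict]:
    """Generate the observed table and its ground-truth record."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_days
    names = [
        f"{sub}_{i + 1}" for sub, m in spec.subsystems.items() for i in range(m)
    ]
    m_total = len(names)
    lam = coupling_schedule(spec)

    # 0..1 progress of the ramp, shared by loading, factor AR and noise gain
    span = spec.coupling_post - spec.coupling_pre
    ramp01 = (lam - spec.coupling_pre) / span if span else np.zeros(n)
    phi = spec.factor_ar + (spec.factor_ar_critical - spec.factor_ar) * ramp01
    gain = 1.0 + (spec.noise_gain_post - 1.0) * ramp01
    g = np.zeros(n)
    factor_innov = rng.normal(size=n)
    for t in range(1, n):
        g[t] = phi[t] * g[t - 1] + gain[t] * factor_innov[t]
    z = np.zeros((n, m_total))
    eps = rng.normal(scale=spec.noise_sd, size=(n, m_total))
    loadings = rng.uniform(0.6, 1.0, size=m_total)  # heterogeneous factor loadings
    for t in range(1, n):
        z[t] = spec.ar * z[t - 1] + lam[t] * loadings * g[t] + eps[t]

    mid = (1 + spec.ordinal_levels) / 2.0
    shift = spec.level_shift * (np.arange(n) >= spec.shift_day)[:, None]
    x = np.clip(
        np.rint(mid + spec.projection_gain * z + shift), 1, spec.ordinal_levels
    ).astype(float)

    n_rev = int(round(spec.reverse_coded_fraction * m_total))
    rev_idx = rng.choice(m_total, size=n_rev, replace=False) if n_rev else np.array([], int)
    x[:, rev_idx] = 1 + spec.ordinal_levels - x[:, rev_idx]
    reverse_coded = frozenset(names[i] for i in rev_idx)

    if spec.missing_rate > 0:
        x[rng.random(size=x.shape) < spec.missing_rate] = np.nan
    if spec.missing_block is not None:
        b0, b1 = spec.missing_block
        x[b0:b1, :] = np.nan

    dates = pd.date_range("2021-01-01", periods=n, freq="D")
    frame = pd.DataFrame(x, index=dates, columns=names)
    subsystem_map = {
        name: name.rsplit("_", 1)[0] for name in names
    }
    table = RawTable(
        frame=frame,
        reverse_coded=reverse_coded,
        subsystem_map=subsystem_map,
        scale_range=(1.0, float(spec.ordinal_levels)),
    )
    truth = {
        "spec": {k: (dict(v) if isinstance(v, dict) else v) for k, v in asdict(spec).items()},
        "shift_day": spec.shift_day,
        "ramp_window": [max(0, spec.shift_day - spec.ramp_days), spec.shift_day],
        "coupling_schedule": lam.tolist(),
        "reverse_coded": sorted(reverse_coded),
        "seed": spec.seed,
    }
    return table, truth


def gen_weekly_state_variable(
    spec: SyntheticSpec,
    base: float = 10.0,
    step: float = 10.0,
    noise: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weekly state scalar stepping up at the first week boundary >= shift.

    Noise is bounded uniform on [-noise, noise].  Returns ``(weekly,
    events)``: the weekly series (day, value) and a single-row events table
    (day, label, direction) marking the step, in the dialect the monitoring
    module consumes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1_000_003)
    days = np.arange(0, spec.n_days, 7)
    step_day = 7 * int(np.ceil(spec.shift_day / 7))
    values = base + step * (days >= step_day)
    if noise > 0:
        values = values + rng.uniform(-noise, noise, size=days.size)
    weekly = pd.DataFrame({"day": days, "value": values})
    events = pd.DataFrame({"day": [step_day], "label": ["state_shift"], "direction": ["up"]})
    return weekly, events


def gen_iid_null(
    n_days: int, subsystems: dict[str, int] | None = None, seed: int = 0
) -> dict[str, np.ndarray]:
    """Reference i.i.d. null: independent standard-normal state vectors.

    Used to calibrate surrogate reference bands — under row exchangeability
    the observed indicator trace is statistically indistinguishable from its
    shuffled surrogates.
    """
    subsystems = subsystems or {"a": 3, "b": 3, "c": 3}
    rng = np.random.default_rng(seed)
    return {name: rng.normal(size=(n_days, m)) for name, m in subsystems.items()}
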