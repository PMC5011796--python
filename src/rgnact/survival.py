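"""Cumulative-hazard estimation and hazard-to-probability conversion.

The cohort model consumes *per-cycle transition probabilities*.  Given
individual patient data (event/censoring times) the cumulative hazard
``H(t)`` is estimated with the Nelson-Aalen estimator (increments ``d_i/n_i``
at each distinct event time, ties aggregated), and converted to the
probability of an event within a cycle of length ``u`` by

    tp(t) = 1 - exp{H(t-u) - H(t)}

A hazard ratio ``tau`` (treatment effect of the guided strategy versus the
conventional one) yields the counterfactual comparator probability

    tp(t; tau) = 1 - exp{(1/tau) * (H(t-u) - H(t))}

so ``tau = 1`` reduces to the unadjusted conversion and smaller ``tau``
(guided arm better) gives a larger comparator probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IPDRecord",
    "CumulativeHazard",
    "nelson_aalen",
    "km_cumulative_hazard",
    "annual_tp",
    "hr_adjusted_tp",
    "tps_from_ipd",
    "read_ipd_csv",
    "write_ipd_csv",
]


@dataclass(frozen=True)
class IPDRecord:
    """One subject: follow-up time in years and event indicator."""

    time: float
    event: bool

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError(f"follow-up time must be positive, got {self.time}")


@dataclass(frozen=True)
class CumulativeHazard:
    """Right-continuous step function H(t) with H(0) = 0.

    ``times`` are the distinct event times (sorted), ``values`` the
    cumulative hazard immediately after each, ``at_risk`` the risk-set size
    just before each event time.
    """

    times: np.ndarray
    values: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("event-time grid must be strictly increasing")
        if np.any(v < 0) or np.any(np.diff(v) < 0):
            raise ValueError("cumulative hazard must be non-negative and non-decreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "at_risk", np.asarray(self.at_risk, float))

    def __call__(self, t):
        """H(t) by right-continuous step extension (0 before the first event)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[0.0], self.values])
        out = padded[idx]
        return float(out) if out.ndim == 0 else out


def _records_to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        times = records["time_years"].to_numpy(float)
        events = records["event"].to_numpy().astype(bool)
    else:
        records = list(records)
        if records and isinstance(records[0], IPDRecord):
            times = np.array([r.time for r in records], float)
            events = np.array([r.event for r in records], bool)
        else:
            times = np.array([t for t, _ in records], float)
            events = np.array([bool(e) for _, e in records], bool)
    if times.size == 0:
        raise ValueError("at least one record is required")
    if np.any(times <= 0):
        raise ValueError("follow-up times must be positive")
    return times, events


def nelson_aalen(records) -> CumulativeHazard:
    """Nelson-Aalen estimate of the cumulative hazard from IPD.

    ``records`` may be an iterable of :class:`IPDRecord`, of ``(time, event)``
    pairs, or a DataFrame with columns ``time_years``/``event``.  Tied events
    are aggregated (increment ``d_i/n_i`` at each distinct event time);
    censored-only input gives the zero hazard.
    """
    times, events = _records_to_arrays(records)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = times.size

    event_times, values, risk = [], [], []
    h = 0.0
    i = 0
    while i < n:
        t = times[i]
        at_risk = n - i
        d = 0
        while i < n and times[i] == t:
            d += int(events[i])
            i += 1
        if d > 0:
            h += d / at_risk
            event_times.append(t)
            values.append(h)
            risk.append(at_risk)
    return CumulativeHazard(
        times=np.asarray(event_times, float),
        values=np.asarray(values, float),
        at_risk=np.asarray(risk, float),
    )


def km_cumulative_hazard(records) -> CumulativeHazard:
    """Alternative estimator: -log of the Kaplan-Meier survival function.

    Provided for comparison with the Nelson-Aalen default; undefined once the
    KM estimate hits zero (the last increment is truncated there).
    """
    times, events = _records_to_arrays(records)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = times.size

    event_times, values, risk = [], [], []
    s = 1.0
    i = 0
    while i < n:
        t = times[i]
        at_risk = n - i
        d = 0
        while i < n and times[i] == t:
            d += int(events[i])
            i += 1
        if d > 0:
            s *= max(1.0 - d / at_risk, 1e-300)
            event_times.append(t)
            values.append(-np.log(s))
            risk.append(at_risk)
    return CumulativeHazard(
        times=np.asarray(event_times, float),
        values=np.asarray(values, float),
        at_risk=np.asarray(risk, float),
    )


def annual_tp(H: CumulativeHazard, year: int, cycle: float = 1.0) -> float:
    """Per-cycle transition probability over the interval ``(year-cycle, year]``."""
    if year < 1:
        raise ValueError(f"cycle year must be >= 1, got {year}")
    delta = H(year * 1.0) - H(year - cycle)
    return float(1.0 - np.exp(-delta))


def hr_adjusted_tp(H: CumulativeHazard, year: int, tau: float, cycle: float = 1.0) -> float:
    """Counterfactual comparator probability under hazard ratio ``tau`` (> 0)."""
    if tau <= 0:
        raise ValueError(f"hazard ratio must be positive, got {tau}")
    if year < 1:
        raise ValueError(f"cycle year must be >= 1, got {year}")
    delta = H(year * 1.0) - H(year - cycle)
    return float(1.0 - np.exp(-delta / tau))


def tps_from_ipd(records, horizon: int = 5, tau: float = 1.0) -> np.ndarray:
    """Yearly transition probabilities tp1..tp_horizon from IPD."""
    H = nelson_aalen(records)
    return np.array([hr_adjusted_tp(H, t, tau) for t in range(1, horizon + 1)])


def read_ipd_csv(path) -> pd.DataFrame:
    """Read IPD from CSV with columns time_years, event (0/1) and optional group."""
    df = pd.read_csv(path)
    required = {"time_years", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"IPD csv must contain columns {sorted(required)}")
    return df


def write_ipd_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
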