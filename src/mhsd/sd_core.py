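"""Deterministic stock-flow integration engine.

Stocks live in a named vector; a *flow field* maps ``(t, stocks, params,
scenario)`` to per-stock net flows (per year) plus any auxiliary variables
(waiting time, prevalence, instantaneous event rates) worth recording at every
step.  Integration is forward Euler on a uniform weekly grid, the step size
system-dynamics tools conventionally use.  Stocks are clamped at zero — a
behavioural rate function may transiently overdraw a small stock at a coarse
step — and the clamped deficit is logged rather than raised.

Time is measured in decimal years with the (days since 1 January)/365.25
convention, so 1 September 2021 is 2021.6653.  One week is 7/365.25 years
everywhere.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WEEK",
    "WEEKS_PER_YEAR",
    "DEFAULT_DT",
    "decimal_year",
    "StockVector",
    "Trajectory",
    "NonFiniteFlowError",
    "integrate",
    "cumulate",
]

#: One week in decimal years.
WEEK = 7.0 / 365.25
#: Number of weeks in one (mean Julian) year.
WEEKS_PER_YEAR = 365.25 / 7.0
#: Default integration step: one week.
DEFAULT_DT = 1.0 / 52.0


def decimal_year(year: int, month: int = 1, day: int = 1) -> float:
    """Convert a calendar date to a decimal year.

    Uses (days elapsed since 1 January)/365.25, so 1 Sep 2021 -> 2021.6653.
    """
    days = (_dt.date(year, month, day) - _dt.date(year, 1, 1)).days
    return year + days / 365.25


class NonFiniteFlowError(RuntimeError):
    """A flow field produced NaN/inf; carries the stock name and time."""

    def __init__(self, stock: str, time: float, value: float):
        self.stock = stock
        self.time = time
        self.value = value
        super().__init__(
            f"non-finite flow {value!r} for stock {stock!r} at t={time:.4f}"
        )


@dataclass
class StockVector:
    """Named nonnegative quantities (persons, or sessions for capacity).

    The set of names is fixed for a given model build; ``values`` is aligned
    with ``names``.
    """

    names: tuple[str, ...]
    values: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.names)} stock names"
            )
        if np.any(self.values < 0):
            bad = self.names[int(np.argmin(self.values))]
            raise ValueError(f"negative initial stock {bad!r}")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def total(self) -> float:
        return float(self.values.sum())

    def copy(self) -> "StockVector":
        return StockVector(self.names, self.values.copy(), self.time)


@dataclass
class Trajectory:
    """Simulation output: uniform time grid, stock matrix, auxiliary series.

    ``aux`` series (waiting time in weeks, prevalence in %, event rates in
    events/week, delivered sessions) share the time grid.  ``clamped`` records
    the total person(-or-session)-deficit absorbed by the zero-clamp, per
    stock.
    """

    times: np.ndarray
    stock_names: tuple[str, ...]
    stocks: np.ndarray  # shape (len(times), n_stocks)
    aux: dict[str, np.ndarray] = field(default_factory=dict)
    clamped: dict[str, float] = field(default_factory=dict)

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def t1(self) -> float:
        return float(self.times[-1])

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def stock(self, name: str) -> np.ndarray:
        return self.stocks[:, self.stock_names.index(name)]

    def state_at(self, t: float) -> StockVector:
        """Stock snapshot at the grid point nearest ``t``."""
        i = int(np.argmin(np.abs(self.times - t)))
        return StockVector(self.stock_names, self.stocks[i].copy(), float(self.times[i]))

    def aux_at(self, name: str, t: float) -> float:
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.aux[name][i])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per time step, one column per stock/auxiliary."""
        data: dict[str, np.ndarray] = {"time": self.times}
        for j, name in enumerate(self.stock_names):
            data[name] = self.stocks[:, j]
        for name, series in self.aux.items():
            data[name] = series
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


FlowField = Callable[[float, np.ndarray, object, object], tuple[np.ndarray, Mapping[str, float] | None]]


def integrate(
    flow_field: FlowField,
    params,
    scenario,
    t0: float,
    t1: float,
    dt: float = DEFAULT_DT,
) -> Trajectory:
    """Forward-Euler integration of ``flow_field`` over ``[t0, t1]``.

    ``params`` must expose ``initial_stocks() -> StockVector``; the flow field
    receives the raw stock array and returns per-stock net flows in units of
    stock per year, plus an optional mapping of auxiliary values recorded at
    the current step.

    Stocks that would go negative are clamped at zero and the deficit is
    accumulated in ``Trajectory.clamped``.  A non-finite flow aborts with the
    offending stock and time.
    """
    if not (t1 > t0):
        raise ValueError(f"t1={t1} must exceed t0={t0}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if dt > (t1 - t0):
        raise ValueError(f"dt={dt} exceeds the span t1-t0={t1 - t0}")

    init = params.initial_stocks()
    names = init.names
    n_steps = int(round((t1 - t0) / dt))
    times = t0 + dt * np.arange(n_steps + 1)
    k = len(names)

    stocks = np.empty((n_steps + 1, k))
    stocks[0] = init.values
    clamped = np.zeros(k)

    aux_store: dict[str, np.ndarray] | None = None
    y = init.values.copy()
    for i in range(n_steps + 1):
        t = float(times[i])
        flows, aux = flow_field(t, y, params, scenario)
        flows = np.asarray(flows, dtype=float)
        if not np.all(np.isfinite(flows)):
            j = int(np.flatnonzero(~np.isfinite(flows))[0])
            raise NonFiniteFlowError(names[j], t, float(flows[j]))
        if aux:
            if aux_store is None:
                aux_store = {name: np.empty(n_steps + 1) for name in aux}
            for name, value in aux.items():
                aux_store[name][i] = value
        if i == n_steps:
            break
        y = y + dt * flows
        neg = y < 0.0
        if neg.any():
            clamped[neg] -= y[neg]
            y[neg] = 0.0
        stocks[i + 1] = y

    clamp_log = {names[j]: float(clamped[j]) for j in range(k) if clamped[j] > 0}
    return Trajectory(times, names, stocks, aux_store or {}, clamp_log)


def cumulate(traj: Trajectory, series_name: str, window: tuple[float, float]) -> float:
    """Time-integral of a rate series over ``window``, in events.

    The named auxiliary series must be an instantaneous rate in events/week;
    the integral uses the trapezoid rule on the simulation grid (with linear
    interpolation at the window endpoints, which makes the integral exactly
    additive over adjacent windows).
    """
    if series_name not in traj.aux:
        raise KeyError(f"no auxiliary series {series_name!r} in trajectory")
    a, b = float(window[0]), float(window[1])
    if b < a:
        raise ValueError(f"window reversed: {window}")
    if a < traj.t0 - 1e-9 or b > traj.t1 + 1e-9:
        raise ValueError(
            f"window {window} outside trajectory span [{traj.t0:.4f}, {traj.t1:.4f}]"
        )
    if b == a:
        return 0.0
    series = traj.aux[series_name]
    # grid points strictly inside the window, plus interpolated endpoints
    inside = (traj.times > a) & (traj.times < b)
    ts = np.concatenate(([a], traj.times[inside], [b]))
    vs = np.concatenate(
        ([np.interp(a, traj.times, series)], series[inside], [np.interp(b, traj.times, series)])
    )
    integral_year = float(np.trapezoid(vs, ts))  # (events/week) * years
    return integral_year * WEEKS_PER_YEAR
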