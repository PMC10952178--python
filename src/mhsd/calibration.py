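"""Calibration: mean absolute proportional deviation (MAPD) minimised by
Powell's direction-set method under box bounds.

The objective is the weighted mean, over every observation in every series,
of |simulated - observed| / observed.  Powell's classic method is
unconstrained, so bounds are imposed by a smooth logit reparameterisation of
each free parameter onto its (lower, upper) interval; the inner optimiser
(scipy's Powell implementation) then searches an unconstrained space and can
never propose an out-of-bounds value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import sector
from .params import ParameterSet
from .scenarios import Scenario, baseline
from .sd_core import DEFAULT_DT, Trajectory, cumulate, integrate

__all__ = ["ObservedSeries", "FitResult", "mapd", "fit", "simulated_observables",
           "read_observed", "write_observed"]


@dataclass
class ObservedSeries:
    """One named historical (or synthetic) calibration series."""

    name: str
    times: np.ndarray  # decimal years, strictly increasing
    values: np.ndarray  # strictly positive (MAPD is undefined at zero)
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError(f"series {self.name!r}: times/values shape mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"series {self.name!r}: times must strictly increase")
        if np.any(self.values <= 0):
            t_bad = float(self.times[int(np.argmin(self.values))])
            raise ValueError(
                f"series {self.name!r}: nonpositive observation at t={t_bad} "
                "(proportional deviation undefined)"
            )
        if self.weight < 0:
            raise ValueError(f"series {self.name!r}: negative weight")


def mapd(simulated: dict[str, np.ndarray], observed: list[ObservedSeries]) -> float:
    """Weighted mean absolute proportional deviation.

    ``simulated[name]`` must be aligned with ``observed`` series ``name``
    (one simulated value per observation time).  Weights are normalised, so
    scaling all weights by a common factor leaves the score unchanged.
    """
    num = 0.0
    den = 0.0
    for series in observed:
        sim = np.asarray(simulated[series.name], dtype=float)
        if sim.shape != series.values.shape:
            raise ValueError(
                f"series {series.name!r}: {sim.shape} simulated values for "
                f"{series.values.shape} observations"
            )
        dev = np.abs(sim - series.values) / series.values
        num += series.weight * float(dev.sum())
        den += series.weight * dev.size
    if den == 0:
        raise ValueError("no observations")
    return num / den


def simulated_observables(
    traj: Trajectory, observed: list[ObservedSeries]
) -> dict[str, np.ndarray]:
    """Model outputs aligned to each series' observation times.

    Annual-count observables (ED presentations, self-harm hospitalisations,
    suicide deaths, delivered sessions) are integrals of the matching rate
    series over the observation's year, taking the observation time as the
    mid-period date; level observables (prevalence) sample the nearest grid
    point.
    """
    out: dict[str, np.ndarray] = {}
    for series in observed:
        if series.name not in sector.OBSERVABLES:
            raise KeyError(
                f"{series.name!r} is not a model observable; known: "
                f"{sorted(sector.OBSERVABLES)}"
            )
        kind, aux_name = sector.OBSERVABLES[series.name]
        vals = np.empty_like(series.times)
        for i, t in enumerate(series.times):
            if kind == "annual_count":
                vals[i] = cumulate(traj, aux_name, (t - 0.5, t + 0.5))
            else:
                vals[i] = traj.aux_at(aux_name, t)
        out[series.name] = vals
    return out


@dataclass
class FitResult:
    """Outcome of a Powell/MAPD calibration."""

    params: ParameterSet
    mapd: float
    initial_mapd: float
    per_series_mapd: dict[str, float]
    free_names: list[str]
    n_iterations: int
    n_evaluations: int
    converged: bool
    on_bounds: list[str] = field(default_factory=list)


def _to_unconstrained(x, lo, hi):
    z = (np.asarray(x) - lo) / (hi - lo)
    return logit(np.clip(z, 1e-12, 1 - 1e-12))


def _to_bounded(z, lo, hi):
    return lo + (hi - lo) * expit(np.asarray(z))


def minimise_bounded(
    objective,
    x0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    ftol: float = 1e-6,
    maxiter: int = 200,
    xtol: float = 1e-4,
):
    """Powell's method on a logit-reparameterised box.

    Returns ``(x, fval, n_iterations, n_evaluations, converged)``.  Exposed
    separately from :func:`fit` so the optimiser can be exercised on
    surrogate objectives.
    """
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    if np.any(lo >= hi):
        raise ValueError("each lower bound must be strictly below its upper bound")
    z0 = _to_unconstrained(np.asarray(x0, dtype=float), lo, hi)

    n_eval = 0

    def wrapped(z):
        nonlocal n_eval
        n_eval += 1
        return objective(_to_bounded(z, lo, hi))

    res = minimize(
        wrapped,
        z0,
        method="Powell",
        options={"ftol": ftol, "xtol": xtol, "maxiter": maxiter, "maxfev": 100_000},
    )
    x = _to_bounded(np.atleast_1d(res.x), lo, hi)
    return x, float(res.fun), int(res.nit), n_eval, bool(res.success)


def fit(
    initial: ParameterSet,
    free_names: list[str] | None,
    observed: list[ObservedSeries],
    scenario: Scenario | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    start: float = 2011.0,
    end: float | None = None,
    dt: float = DEFAULT_DT,
    ftol: float = 1e-6,
    maxiter: int = 200,
    xtol: float = 1e-4,
) -> FitResult:
    """Fit the named free parameters to the observed series by bounded
    Powell search on the MAPD objective.

    ``free_names`` defaults to the parameters flagged ``source=calibrated``
    in the parameter metadata; an empty list is a no-op fit that simply
    scores ``initial``.  Deterministic given the same start point.
    """
    if free_names is None:
        free_names = ParameterSet.calibrated_names()
    for name in free_names:
        initial[name]  # raises KeyError for unknown parameters
    scenario = scenario or baseline(initial)
    if end is None:
        end = max(float(s.times[-1]) for s in observed) + 0.6

    def run(params: ParameterSet) -> Trajectory:
        return integrate(sector.flow_field, params, scenario, start, end, dt)

    def score(params: ParameterSet) -> float:
        return mapd(simulated_observables(run(params), observed), observed)

    def per_series(params: ParameterSet) -> dict[str, float]:
        sims = simulated_observables(run(params), observed)
        return {s.name: mapd({s.name: sims[s.name]}, [s]) for s in observed}

    initial_score = score(initial)
    if not np.isfinite(initial_score):
        raise ValueError(
            f"objective non-finite at the start point (MAPD={initial_score}); "
            f"check parameters {free_names} and the observed series"
        )
    if not free_names:
        return FitResult(
            params=initial,
            mapd=initial_score,
            initial_mapd=initial_score,
            per_series_mapd=per_series(initial),
            free_names=[],
            n_iterations=0,
            n_evaluations=1,
            converged=True,
        )

    all_bounds = dict(
        zip(free_names, ParameterSet.bounds_for(free_names), strict=True)
    )
    if bounds:
        all_bounds.update(bounds)
    lo = np.array([all_bounds[n][0] for n in free_names])
    hi = np.array([all_bounds[n][1] for n in free_names])
    x0 = np.clip(np.array([initial[n] for n in free_names]), lo, hi)

    def objective(x: np.ndarray) -> float:
        return score(initial.replace(**dict(zip(free_names, x))))

    x, fval, nit, nfev, converged = minimise_bounded(
        objective, x0, lo, hi, ftol=ftol, maxiter=maxiter, xtol=xtol
    )
    # Powell tracks the best point seen, so fval <= initial_score; keep the
    # start point in the degenerate case where it was already optimal.
    if fval > initial_score:
        x, fval = x0, initial_score
    fitted = initial.replace(**dict(zip(free_names, x)))
    tol = 1e-6 * (hi - lo)
    on_bounds = [
        n
        for n, xi, l, h, ti in zip(free_names, x, lo, hi, tol)
        if xi - l < ti or h - xi < ti
    ]
    return FitResult(
        params=fitted,
        mapd=fval,
        initial_mapd=initial_score,
        per_series_mapd=per_series(fitted),
        free_names=list(free_names),
        n_iterations=nit,
        n_evaluations=nfev,
        converged=converged,
        on_bounds=on_bounds,
    )


# --------------------------------------------------------------------------
# observed-series file dialect: tab-separated (series, date, value, weight)


def write_observed(observed: list[ObservedSeries], path) -> None:
    with open(path, "w") as fh:
        fh.write("series\tdate\tvalue\tweight\n")
        for s in observed:
            for t, v in zip(s.times, s.values):
                fh.write(f"{s.name}\t{t:.6f}\t{v:.6f}\t{s.weight:g}\n")


def read_observed(path) -> list[ObservedSeries]:
    rows: dict[str, list[tuple[float, float, float]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("series"):
            raise ValueError(f"{path}: expected 'series\\tdate\\tvalue\\tweight' header")
        for line in fh:
            if not line.strip():
                continue
            name, date, value, weight = line.rstrip("\n").split("\t")
            rows.setdefault(name, []).append((float(date), float(value), float(weight)))
    out = []
    for name, triples in rows.items():
        triples.sort()
        out.append(
            ObservedSeries(
                name,
                np.array([t for t, _, _ in triples]),
                np.array([v for _, v, _ in triples]),
                weight=triples[0][2],
            )
        )
    return out
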