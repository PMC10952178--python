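"""Model/Results surface for the care-access system dynamics model.

:class:`CareSystemModel` binds a parameterisation to (optionally) observed
calibration series; :meth:`CareSystemModel.fit` runs the bounded
Powell/MAPD calibration and returns a :class:`CalibrationResults` carrying
the estimates, fit diagnostics and a ``summary()`` table.  Simulation,
impact tables and frontier sweeps hang off both objects.

Example
-------
>>> from mhsd import CareSystemModel, make_scenario
>>> model = CareSystemModel.reference()
>>> tab = model.impact(make_scenario({"direct_access": 0.1}))
>>> print(tab.to_text())          # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np

from . import calibration, reporting, sector
from .calibration import FitResult, ObservedSeries
from .params import PARAM_META, ParameterSet
from .scenarios import Scenario, baseline
from .sd_core import DEFAULT_DT, Trajectory

__all__ = ["CareSystemModel", "CalibrationResults"]


class CareSystemModel:
    """System dynamics model of access to subsidised specialist mental
    health care, bound to a parameterisation and optional observed data.

    Parameters
    ----------
    params
        Model parameterisation; defaults to the shipped reference set.
    observed
        Calibration series (historical or synthetic); required for ``fit``.
    scenario
        The scenario under which calibration runs are made; defaults to the
        historical-era baseline (COVID shocks and JobKeeper on, no levers).
    """

    def __init__(
        self,
        params: ParameterSet | None = None,
        observed: list[ObservedSeries] | None = None,
        scenario: Scenario | None = None,
    ):
        self.params = params if params is not None else ParameterSet.reference()
        self.observed = list(observed) if observed else []
        self.scenario = scenario or baseline(self.params)

    @classmethod
    def reference(cls) -> "CareSystemModel":
        """The shipped reference parameterisation, no observed data."""
        return cls(ParameterSet.reference())

    @classmethod
    def from_files(cls, params_path, observed_path=None) -> "CareSystemModel":
        params = ParameterSet.from_file(params_path)
        observed = calibration.read_observed(observed_path) if observed_path else None
        return cls(params, observed)

    # ----------------------------------------------------------- simulation
    def simulate(
        self,
        scenario: Scenario | None = None,
        start: float = 2011.0,
        end: float = 2029.0,
        dt: float = DEFAULT_DT,
    ) -> Trajectory:
        return reporting.run_scenario(
            self.params, scenario or self.scenario, start, end, dt
        )

    def impact(
        self,
        scenario: Scenario,
        window: tuple[float, float] = reporting.REPORT_WINDOW,
        dt: float = DEFAULT_DT,
    ) -> reporting.ImpactTable:
        base = self.simulate(baseline(self.params), dt=dt)
        scen = self.simulate(scenario, dt=dt)
        return reporting.impact(base, scen, window, scenario.name)

    def frontier(
        self, growth_multiplier: float, d_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5), **kw
    ) -> reporting.FrontierResult:
        return reporting.sweep_frontier(self.params, growth_multiplier, d_grid, **kw)

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        free_names: list[str] | None = None,
        bounds: dict[str, tuple[float, float]] | None = None,
        **options,
    ) -> "CalibrationResults":
        """Calibrate the free parameters against the bound observed series
        (bounded Powell search minimising MAPD)."""
        if not self.observed:
            raise ValueError("model has no observed series bound; pass `observed`")
        result = calibration.fit(
            self.params, free_names, self.observed, self.scenario, bounds, **options
        )
        return CalibrationResults(self, result)


class CalibrationResults:
    """Results of a Powell/MAPD calibration: fitted parameters, objective
    diagnostics, and the same simulation surface as the model."""

    def __init__(self, model: CareSystemModel, result: FitResult):
        self.model = model
        self._result = result
        self.params = result.params
        self.mapd = result.mapd
        self.initial_mapd = result.initial_mapd
        self.per_series_mapd = result.per_series_mapd
        self.converged = result.converged
        self.n_iterations = result.n_iterations
        self.on_bounds = result.on_bounds
        self.free_names = result.free_names

    def as_model(self) -> CareSystemModel:
        return CareSystemModel(self.params, self.model.observed, self.model.scenario)

    def simulate(self, scenario: Scenario | None = None, **kw) -> Trajectory:
        return self.as_model().simulate(scenario, **kw)

    def impact(self, scenario: Scenario, **kw) -> reporting.ImpactTable:
        return self.as_model().impact(scenario, **kw)

    def summary(self) -> str:
        r = self._result
        lines = [
            "Care-access system dynamics model - Powell/MAPD calibration",
            "=" * 66,
            f"{'MAPD (fitted)':<28s}{self.mapd:>12.6f}",
            f"{'MAPD (at start point)':<28s}{self.initial_mapd:>12.6f}",
            f"{'Powell iterations':<28s}{self.n_iterations:>12d}",
            f"{'objective evaluations':<28s}{r.n_evaluations:>12d}",
            f"{'converged':<28s}{str(self.converged):>12s}",
            "",
            f"{'parameter':<24s}{'estimate':>14s}{'lower':>12s}{'upper':>12s}  unit",
            "-" * 66,
        ]
        for name in self.free_names:
            meta = PARAM_META[name]
            flag = "  (on bound)" if name in self.on_bounds else ""
            lines.append(
                f"{name:<24s}{self.params[name]:>14.6g}{meta.lower:>12.4g}"
                f"{meta.upper:>12.4g}  {meta.unit}{flag}"
            )
        lines.append("-" * 66)
        lines.append("per-series MAPD:")
        for name, value in self.per_series_mapd.items():
            lines.append(f"  {name:<32s}{value:>12.6f}")
        return "\n".join(lines)
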