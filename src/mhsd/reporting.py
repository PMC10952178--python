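"""Scenario execution, impact tables, and the direct-access/growth frontier.

The impact of an intervention is the difference between baseline and
scenario in the cumulative number of events over the reporting window
(1 September 2021 - 1 September 2028 by default), per outcome and per
stratum (all ages, 15-24 years).  Negative differences are events averted.

The frontier sweep fixes a capacity-growth multiplier, evaluates a grid of
direct-access fractions (growth from 1 Jan 2022, direct access from
1 Jan 2024), and reports the percentage of baseline ED presentations averted
at each grid point; beyond the optimum the service system saturates and the
benefit declines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sector
from .params import ParameterSet
from .scenarios import Scenario, baseline, make_scenario
from .sd_core import DEFAULT_DT, Trajectory, cumulate, decimal_year, integrate

__all__ = [
    "REPORT_WINDOW",
    "OUTCOMES",
    "STRATA",
    "run_scenario",
    "ImpactTable",
    "impact",
    "FrontierResult",
    "sweep_frontier",
]

#: Default reporting window: 1 Sep 2021 - 1 Sep 2028.
REPORT_WINDOW = (decimal_year(2021, 9, 1), decimal_year(2028, 9, 1))

OUTCOMES = {
    "ed": "Emergency department presentations (mental health)",
    "selfharm": "Hospitalisations with self-harm",
    "suicide": "Deaths by suicide",
}
STRATA = {"all": "all ages", "15_24": "15-24 years"}


def run_scenario(
    params: ParameterSet,
    scenario: Scenario,
    start: float = 2011.0,
    end: float = 2029.0,
    dt: float = DEFAULT_DT,
) -> Trajectory:
    """Integrate the sector model under one scenario."""
    return integrate(sector.flow_field, params, scenario, start, end, dt)


@dataclass
class ImpactTable:
    """Cumulative baseline vs scenario events per outcome and stratum."""

    table: pd.DataFrame  # columns: outcome, stratum, baseline, scenario,
    #                                difference, pct_of_baseline
    window: tuple[float, float]
    scenario_name: str

    def row(self, outcome: str, stratum: str) -> pd.Series:
        t = self.table
        match = t[(t.outcome == outcome) & (t.stratum == stratum)]
        if match.empty:
            raise KeyError(f"no row for ({outcome}, {stratum})")
        return match.iloc[0]

    def averted(self, outcome: str = "ed", stratum: str = "all") -> float:
        """Events averted (positive when the scenario reduces events)."""
        return -float(self.row(outcome, stratum)["difference"])

    def averted_pct(self, outcome: str = "ed", stratum: str = "all") -> float:
        return -float(self.row(outcome, stratum)["pct_of_baseline"])

    def to_text(self) -> str:
        """Presentation table: counts rounded to integers, percentages to
        two decimals (rounding happens only here, never internally)."""
        lines = [
            f"Impact of scenario {self.scenario_name!r}, "
            f"window {self.window[0]:.4f}-{self.window[1]:.4f} "
            "(negative difference = events averted)",
            f"{'outcome':<45s} {'stratum':<12s} {'baseline':>12s} "
            f"{'scenario':>12s} {'diff':>10s} {'pct':>8s}",
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"{OUTCOMES[r.outcome]:<45s} {STRATA[r.stratum]:<12s} "
                f"{r.baseline:>12.0f} {r.scenario:>12.0f} "
                f"{r.difference:>+10.0f} {r.pct_of_baseline:>+7.2f}%"
            )
        return "\n".join(lines)


def impact(
    baseline_traj: Trajectory,
    scenario_traj: Trajectory,
    window: tuple[float, float] = REPORT_WINDOW,
    scenario_name: str = "scenario",
) -> ImpactTable:
    """Tabulate cumulative events in both runs over ``window``."""
    if baseline_traj.times.shape != scenario_traj.times.shape or not np.allclose(
        baseline_traj.times, scenario_traj.times
    ):
        raise ValueError("baseline and scenario trajectories use different grids")
    rows = []
    for outcome in OUTCOMES:
        for stratum in STRATA:
            series = f"{outcome}_{stratum}"
            base = cumulate(baseline_traj, series, window)
            scen = cumulate(scenario_traj, series, window)
            diff = scen - base
            rows.append(
                {
                    "outcome": outcome,
                    "stratum": stratum,
                    "baseline": base,
                    "scenario": scen,
                    "difference": diff,
                    "pct_of_baseline": 100.0 * diff / base if base else 0.0,
                }
            )
    return ImpactTable(pd.DataFrame(rows), tuple(window), scenario_name)


@dataclass
class FrontierResult:
    """Averted-ED percentage along a direct-access grid at fixed growth."""

    growth_multiplier: float
    d_grid: np.ndarray
    averted_ed_pct: np.ndarray
    optimal_d: float
    saturated: bool  # an evaluated point beyond the optimum does worse

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "direct_access": self.d_grid,
                "averted_ed_pct": self.averted_ed_pct,
                "optimal": np.isclose(self.d_grid, self.optimal_d),
            }
        )


def sweep_frontier(
    params: ParameterSet,
    growth_multiplier: float,
    d_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    window: tuple[float, float] = REPORT_WINDOW,
    baseline_traj: Trajectory | None = None,
    dt: float = DEFAULT_DT,
) -> FrontierResult:
    """Evaluate the averted-ED frontier over a direct-access grid.

    Growth starts 1 Jan 2022 and direct access 1 Jan 2024 (the combined-
    scenario convention).  The optimum is the argmax on the grid, ties broken
    toward smaller direct-access fractions.
    """
    if growth_multiplier < 1:
        raise ValueError("growth multiplier must be >= 1")
    d_grid = np.asarray(sorted(d_grid), dtype=float)
    if d_grid[0] != 0.0 or d_grid[-1] > 0.5 or d_grid[0] < 0.0:
        raise ValueError("d_grid must lie within [0, 0.5] and include 0")
    if baseline_traj is None:
        baseline_traj = run_scenario(params, baseline(params), dt=dt)
    averted = np.empty_like(d_grid)
    for i, d in enumerate(d_grid):
        spec: dict = {"name": f"frontier_m{growth_multiplier}_d{d:g}"}
        if growth_multiplier > 1:
            spec["growth_multiplier"] = growth_multiplier
        if d > 0:
            spec["direct_access"] = d
            spec["direct_access_start"] = 2024.0
        scen = make_scenario(spec, params)
        traj = run_scenario(params, scen, dt=dt)
        averted[i] = impact(baseline_traj, traj, window).averted_pct("ed", "all")
    best = int(np.argmax(averted))  # np.argmax returns the first (smallest d) tie
    return FrontierResult(
        growth_multiplier=float(growth_multiplier),
        d_grid=d_grid,
        averted_ed_pct=averted,
        optimal_d=float(d_grid[best]),
        saturated=best < d_grid.size - 1,
    )
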