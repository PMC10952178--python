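"""Policy scenarios: dated levers applied as time-varying modifiers.

A :class:`Scenario` bundles the service-provision levers explored by the
model — the direct-access fraction (people who can book subsidised specialist
sessions without a GP referral), the acceleration multiplier on the linear
growth of specialist session capacity, a demand uplift on the perceived-need
fraction — together with the baseline-era features every run shares: the
COVID-era distress shocks, the JobKeeper damping of the employment
disruption, and the temporarily extended Better Access session cap
(20 sessions/year instead of 10).

All switches are encoded as half-open intervals ``[start, end)`` in decimal
years: a policy that "ends 31 December 2022" still applies on that day and
stops at 2023.0.  Lever start-date defaults follow the published scenario
grid: levers start 1 Jan 2022, except that when direct access is combined
with accelerated capacity growth its start moves to 1 Jan 2024 (allowing
capacity to grow first), and the demand uplift always starts 1 Jan 2024.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .params import ParameterSet
from .sd_core import decimal_year

__all__ = [
    "SIM_START",
    "SIM_END",
    "Scenario",
    "ModifierBundle",
    "make_scenario",
    "modifier_at",
    "baseline",
    "scenario_library",
    "load_scenario_file",
    "save_scenario_file",
]

SIM_START = 2011.0
SIM_END = 2029.0

# COVID-era windows (decimal years); magnitudes live in the parameter file.
COVID_PEAK_WINDOW = (decimal_year(2020, 4, 1), 2021.0)
COVID_LATE_WINDOW = (2021.0, 2022.0)
EMPLOYMENT_DISRUPTION_WINDOW = (decimal_year(2020, 4, 1), decimal_year(2021, 10, 1))
# JobKeeper wage subsidy operated April 2020 - March 2021.
JOBKEEPER_WINDOW = (decimal_year(2020, 4, 1), decimal_year(2021, 4, 1))

# Better Access extension (20 sessions/year): introduced during the pandemic,
# ended 31 December 2022 in the baseline (optionally retained through 2023).
BA_EXTENSION_START = decimal_year(2020, 8, 9)
BA_EXTENSION_END = 2023.0
BA_EXTENSION_END_RETAINED = 2024.0
BA_CAP_NORMAL = 10.0
BA_CAP_EXTENDED = 20.0

_LEVER_START_DEFAULT = 2022.0
_COMBINED_START_DEFAULT = 2024.0


@dataclass(frozen=True)
class Scenario:
    """Fully-dated policy configuration for one simulation run."""

    name: str = "baseline"
    direct_access: float = 0.0  # fraction d of seekers bypassing GP referral
    direct_access_start: float = _LEVER_START_DEFAULT
    growth_multiplier: float = 1.0  # m, applied to the capacity slope
    growth_start: float = _LEVER_START_DEFAULT
    demand_uplift: float = 0.0  # relative uplift of the perceived-need fraction
    demand_uplift_start: float = _COMBINED_START_DEFAULT
    ba_extension_end: float = BA_EXTENSION_END
    covid: bool = True
    jobkeeper: bool = True
    # COVID magnitudes, copied from the parameter file at construction so a
    # Scenario is self-contained.
    covid_onset_mult_peak: float = 1.30
    covid_onset_mult_late: float = 1.15
    covid_employment_onset: float = 0.10
    jobkeeper_damping: float = 0.5
    audit: tuple[str, ...] = field(default_factory=tuple, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.direct_access <= 0.5):
            raise ValueError(
                f"direct_access must lie in [0, 0.5], got {self.direct_access}"
            )
        if self.growth_multiplier < 1.0:
            raise ValueError(
                f"growth_multiplier must be >= 1 (only acceleration is "
                f"modelled), got {self.growth_multiplier}"
            )
        if not (0.0 <= self.demand_uplift <= 0.10):
            raise ValueError(
                f"demand_uplift must lie in [0, 0.10], got {self.demand_uplift}"
            )
        for label, t in (
            ("direct_access_start", self.direct_access_start),
            ("growth_start", self.growth_start),
            ("demand_uplift_start", self.demand_uplift_start),
            ("ba_extension_end", self.ba_extension_end),
        ):
            if not (SIM_START <= t <= SIM_END):
                raise ValueError(
                    f"{label}={t} outside simulation span [{SIM_START}, {SIM_END}]"
                )

    def is_baseline(self) -> bool:
        return (
            self.direct_access == 0.0
            and self.growth_multiplier == 1.0
            and self.demand_uplift == 0.0
        )


@dataclass(frozen=True)
class ModifierBundle:
    """Piecewise-constant lever values in force at one instant."""

    perceived_need_mult: float
    onset_mult: float
    session_cap: float
    direct_access: float
    growth_multiplier: float


_SCENARIO_KEYS = {
    "name",
    "direct_access",
    "direct_access_start",
    "growth_multiplier",
    "growth_start",
    "demand_uplift",
    "demand_uplift_start",
    "ba_extended_until_2023",
    "covid",
    "jobkeeper",
}


def make_scenario(spec: dict | None = None, params: ParameterSet | None = None) -> Scenario:
    """Build a fully-dated :class:`Scenario` from a key-value specification.

    Unknown keys and out-of-range values are rejected; every default applied
    is echoed in ``Scenario.audit``.  When direct access is combined with
    accelerated growth and no explicit start date is given, its start
    defaults to 1 Jan 2024 rather than 1 Jan 2022.
    """
    spec = dict(spec or {})
    unknown = set(spec) - _SCENARIO_KEYS
    if unknown:
        raise KeyError(f"unknown scenario key(s): {sorted(unknown)}")
    params = params or ParameterSet()
    audit: list[str] = []

    kwargs: dict = {
        "covid_onset_mult_peak": params.covid_onset_mult_peak,
        "covid_onset_mult_late": params.covid_onset_mult_late,
        "covid_employment_onset": params.covid_employment_onset,
        "jobkeeper_damping": params.jobkeeper_damping,
    }
    kwargs["name"] = spec.get("name", "scenario" if spec else "baseline")

    d = float(spec.get("direct_access", 0.0))
    m = float(spec.get("growth_multiplier", 1.0))
    kwargs["direct_access"] = d
    kwargs["growth_multiplier"] = m
    if "direct_access" not in spec:
        audit.append("direct_access defaulted to 0")
    if "growth_multiplier" not in spec:
        audit.append("growth_multiplier defaulted to 1")

    if "direct_access_start" in spec:
        kwargs["direct_access_start"] = float(spec["direct_access_start"])
    elif d > 0 and m > 1:
        kwargs["direct_access_start"] = _COMBINED_START_DEFAULT
        audit.append(
            "direct_access_start defaulted to 2024.0 (combined with growth)"
        )
    else:
        kwargs["direct_access_start"] = _LEVER_START_DEFAULT
        audit.append("direct_access_start defaulted to 2022.0")

    kwargs["growth_start"] = float(spec.get("growth_start", _LEVER_START_DEFAULT))
    if "growth_start" not in spec:
        audit.append("growth_start defaulted to 2022.0")

    kwargs["demand_uplift"] = float(spec.get("demand_uplift", 0.0))
    if "demand_uplift" not in spec:
        audit.append("demand_uplift defaulted to 0")
    kwargs["demand_uplift_start"] = float(
        spec.get("demand_uplift_start", _COMBINED_START_DEFAULT)
    )
    if "demand_uplift_start" not in spec:
        audit.append("demand_uplift_start defaulted to 2024.0")

    if spec.get("ba_extended_until_2023", False):
        kwargs["ba_extension_end"] = BA_EXTENSION_END_RETAINED
    else:
        audit.append("Better Access extension ends 31 Dec 2022 (default)")

    kwargs["covid"] = bool(spec.get("covid", True))
    kwargs["jobkeeper"] = bool(spec.get("jobkeeper", True))
    kwargs["audit"] = tuple(audit)
    return Scenario(**kwargs)


def baseline(params: ParameterSet | None = None, **flags) -> Scenario:
    """The baseline scenario: no levers, COVID shocks and JobKeeper on,
    Better Access extension ending 31 Dec 2022."""
    return make_scenario({"name": "baseline", **flags}, params)


def modifier_at(scenario: Scenario, t: float) -> ModifierBundle:
    """The lever bundle in force at time ``t`` (piecewise-constant; switches
    exactly at configured dates, half-open ``[start, end)`` intervals)."""
    # perceived-need multiplier
    need = 1.0
    if scenario.demand_uplift > 0 and t >= scenario.demand_uplift_start:
        need = 1.0 + scenario.demand_uplift
    # distress-onset multiplier from COVID shocks
    onset = 1.0
    if scenario.covid:
        if COVID_PEAK_WINDOW[0] <= t < COVID_PEAK_WINDOW[1]:
            onset = scenario.covid_onset_mult_peak
        elif COVID_LATE_WINDOW[0] <= t < COVID_LATE_WINDOW[1]:
            onset = scenario.covid_onset_mult_late
        if EMPLOYMENT_DISRUPTION_WINDOW[0] <= t < EMPLOYMENT_DISRUPTION_WINDOW[1]:
            add = scenario.covid_employment_onset
            if scenario.jobkeeper and JOBKEEPER_WINDOW[0] <= t < JOBKEEPER_WINDOW[1]:
                add *= 1.0 - scenario.jobkeeper_damping
            onset += add
    # Better Access session cap
    cap = BA_CAP_NORMAL
    if BA_EXTENSION_START <= t < scenario.ba_extension_end:
        cap = BA_CAP_EXTENDED
    # direct access and growth multiplier
    d = scenario.direct_access if t >= scenario.direct_access_start else 0.0
    m = scenario.growth_multiplier if t >= scenario.growth_start else 1.0
    return ModifierBundle(need, onset, cap, d, m)


def switch_dates(scenario: Scenario) -> list[float]:
    """Every date at which the modifier bundle may change (for testing the
    piecewise-constant property and for exact-stepping diagnostics)."""
    dates = {
        scenario.direct_access_start,
        scenario.growth_start,
        scenario.demand_uplift_start,
        BA_EXTENSION_START,
        scenario.ba_extension_end,
    }
    if scenario.covid:
        dates.update(
            [
                *COVID_PEAK_WINDOW,
                *COVID_LATE_WINDOW,
                *EMPLOYMENT_DISRUPTION_WINDOW,
                *JOBKEEPER_WINDOW,
            ]
        )
    return sorted(dates)


# --------------------------------------------------------------------------
# scenario files and the shipped library of printed scenarios


def save_scenario_file(scenario_spec: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_spec, fh, sort_keys=False)


def load_scenario_file(path, params: ParameterSet | None = None) -> Scenario:
    with open(path) as fh:
        spec = yaml.safe_load(fh) or {}
    if not isinstance(spec, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    return make_scenario(spec, params)


def scenario_library(params: ParameterSet | None = None) -> dict[str, Scenario]:
    """The printed scenario grid: three direct-access-alone scenarios, the
    eight growth/combination scenarios, and the baseline."""
    lib: dict[str, Scenario] = {"baseline": baseline(params)}
    for d in (0.10, 0.20, 0.50):
        lib[f"direct_{int(d * 100)}"] = make_scenario(
            {"name": f"direct_{int(d * 100)}", "direct_access": d}, params
        )
    grid = [
        (2, 0.0, 0.0),
        (2, 0.10, 0.0),
        (3, 0.0, 0.0),
        (3, 0.20, 0.0),
        (3, 0.20, 0.05),
        (5, 0.0, 0.0),
        (5, 0.50, 0.0),
        (5, 0.50, 0.10),
    ]
    for m, d, u in grid:
        name = f"growth_{m}"
        if d > 0:
            name += f"_direct_{int(d * 100)}"
        if u > 0:
            name += f"_uplift_{int(u * 100)}"
        lib[name] = make_scenario(
            {
                "name": name,
                "growth_multiplier": m,
                "direct_access": d,
                "demand_uplift": u,
            },
            params,
        )
    return lib
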