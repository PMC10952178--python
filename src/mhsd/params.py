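"""Model parameters: rate constants, initial conditions, capacity, behaviour.

A :class:`ParameterSet` is the calibrated object — every rate constant,
initial stock level, the linear capacity ramp, and the behavioural-response
coefficients of the care pathway.  Each parameter carries metadata (unit,
bounds used by the calibrator, provenance) in :data:`PARAM_META`; the shipped
reference parameterisation lives in ``data/reference_parameters.tsv`` and is
read back with :func:`ParameterSet.reference`.

Provenance labels:

``supplementary``
    taken directly from published figures (e.g. mean 4.5 subsidised sessions
    per user).
``calibrated``
    estimated by this repository's own constrained-optimisation calibration
    against historical-era aggregates; these are the parameters the fitter
    frees by default.
``assumed``
    structural or demographic values fixed from public aggregates or stated
    modelling assumptions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

__all__ = ["ParamMeta", "PARAM_META", "ParameterSet"]


@dataclass(frozen=True)
class ParamMeta:
    default: float
    unit: str
    lower: float
    upper: float
    source: str  # supplementary | calibrated | assumed


def _m(default, unit, lower, upper, source) -> ParamMeta:
    return ParamMeta(float(default), unit, float(lower), float(upper), source)


# name -> (default, unit, lower bound, upper bound, source)
PARAM_META: dict[str, ParamMeta] = {
    # --- demography (2011 initial populations and flows) -------------------
    "pop_0_14_2011": _m(1.37e6, "persons", 1.0e6, 1.8e6, "assumed"),
    "pop_15_24_2011": _m(0.95e6, "persons", 0.7e6, 1.2e6, "assumed"),
    "pop_25p_2011": _m(4.90e6, "persons", 4.0e6, 6.0e6, "assumed"),
    "entry_children": _m(95_000.0, "persons/year", 50_000.0, 150_000.0, "assumed"),
    "entry_adults": _m(85_000.0, "persons/year", 0.0, 200_000.0, "assumed"),
    "ageing_0_14": _m(1.0 / 15.0, "1/year", 0.05, 0.1, "assumed"),
    "ageing_15_24": _m(0.10, "1/year", 0.08, 0.12, "assumed"),
    "exit_0_14": _m(0.002, "1/year", 0.0, 0.01, "assumed"),
    "exit_15_24": _m(0.004, "1/year", 0.0, 0.01, "assumed"),
    "exit_25p": _m(0.0155, "1/year", 0.005, 0.03, "assumed"),
    # --- initial distress prevalence and care-state occupancy --------------
    "init_prev_0_14": _m(20.0, "%", 5.0, 40.0, "calibrated"),
    "init_prev_15_24": _m(29.0, "%", 10.0, 50.0, "calibrated"),
    "init_prev_25p": _m(26.0, "%", 10.0, 45.0, "calibrated"),
    "init_frac_waiting": _m(0.02, "fraction of distressed", 0.0, 0.2, "assumed"),
    "init_frac_gp": _m(0.05, "fraction of distressed", 0.0, 0.3, "assumed"),
    "init_frac_spec": _m(0.04, "fraction of distressed", 0.0, 0.3, "assumed"),
    "init_frac_diseng": _m(0.06, "fraction of distressed", 0.0, 0.3, "assumed"),
    "init_frac_recov": _m(0.02, "fraction of low-distress", 0.0, 0.2, "assumed"),
    # --- psychological-distress dynamics ------------------------------------
    "onset_0_14": _m(0.14, "1/year", 0.01, 0.6, "calibrated"),
    "onset_15_24": _m(0.42, "1/year", 0.02, 1.2, "calibrated"),
    "onset_25p": _m(0.18, "1/year", 0.02, 0.8, "calibrated"),
    "onset_trend": _m(0.27, "fraction/year", 0.0, 0.6, "calibrated"),
    "onset_trend_end": _m(2019.0, "decimal year", 2015.0, 2022.0, "assumed"),
    "remission": _m(0.45, "1/year", 0.05, 2.0, "calibrated"),
    # --- help seeking and the GP pathway ------------------------------------
    "perceived_need": _m(0.55, "fraction", 0.1, 1.0, "calibrated"),
    "help_seek_rate": _m(0.7213, "1/year", 0.1, 3.0, "calibrated"),
    "seek_trend": _m(0.02, "fraction/year", 0.0, 0.05, "calibrated"),
    "seek_trend_end": _m(2022.0, "decimal year", 2015.0, 2029.0, "assumed"),
    "gp_referral_fraction": _m(0.517, "fraction", 0.1, 0.9, "calibrated"),
    "gp_recovery": _m(1.20, "1/year", 0.2, 6.0, "assumed"),
    "gp_return": _m(1.80, "1/year", 0.1, 6.0, "assumed"),
    # --- specialist care and capacity ---------------------------------------
    "sessions_per_user": _m(4.5, "sessions/user", 1.0, 10.0, "supplementary"),
    "treatment_recovery": _m(4.0, "1/year", 0.5, 12.0, "assumed"),
    "intake_sessions": _m(1.0, "sessions/admission", 0.0, 5.0, "assumed"),
    "admit_time": _m(0.02, "years", 0.01, 0.25, "assumed"),
    "cap_demand_elasticity": _m(0.15, "dimensionless", 0.0, 1.0, "assumed"),
    "capacity_2011": _m(2.5503e6, "sessions/year", 1.0e6, 1.0e7, "calibrated"),
    "capacity_slope": _m(120_922.0, "sessions/year^2", 1.0e4, 1.0e6, "calibrated"),
    # --- waiting, disengagement, re-engagement ------------------------------
    "wait_ref": _m(4.0, "weeks", 1.0, 26.0, "assumed"),
    "wait_cap": _m(104.0, "weeks", 26.0, 208.0, "assumed"),
    "disengage_coeff": _m(0.025, "1/week", 0.001, 0.5, "calibrated"),
    "reengage_rate": _m(0.80, "1/year", 0.1, 4.0, "assumed"),
    "reengage_seek_rate": _m(4.0, "1/year", 0.0, 6.0, "assumed"),
    "recovery_fade": _m(1.50, "1/year", 0.2, 6.0, "assumed"),
    # --- adverse-outcome rate coefficients (per person in moderate+ distress,
    #     not seeking care; care-state multipliers below scale these) --------
    "ed_rate_0_14": _m(0.0195773, "events/person/year", 1e-4, 0.2, "calibrated"),
    "ed_rate_15_24": _m(0.0393437, "events/person/year", 1e-4, 0.3, "calibrated"),
    "ed_rate_25p": _m(0.029366, "events/person/year", 1e-4, 0.3, "calibrated"),
    "selfharm_rate_0_14": _m(0.00108662, "events/person/year", 1e-6, 0.05, "calibrated"),
    "selfharm_rate_15_24": _m(0.00511974, "events/person/year", 1e-6, 0.05, "calibrated"),
    "selfharm_rate_25p": _m(0.00227202, "events/person/year", 1e-6, 0.05, "calibrated"),
    "suicide_rate_0_14": _m(1.16789e-5, "events/person/year", 1e-8, 0.01, "calibrated"),
    "suicide_rate_15_24": _m(2.45818e-4, "events/person/year", 1e-8, 0.01, "calibrated"),
    "suicide_rate_25p": _m(3.601e-4, "events/person/year", 1e-8, 0.01, "calibrated"),
    # --- care-state multipliers on the outcome coefficients -----------------
    # ordering constraint: disengaged > waiting > (not seeking) > GP > specialist
    "outmult_waiting": _m(1.15, "dimensionless", 1.0, 3.0, "assumed"),
    "outmult_gp": _m(0.85, "dimensionless", 0.1, 1.0, "assumed"),
    "outmult_spec": _m(0.45, "dimensionless", 0.1, 1.0, "assumed"),
    "diseng_escalation": _m(1.6, "dimensionless", 1.0, 5.0, "calibrated"),
    # --- COVID-era exogenous shocks (magnitudes; dates live in scenarios) ---
    "covid_onset_mult_peak": _m(1.30, "dimensionless", 1.0, 2.0, "assumed"),
    "covid_onset_mult_late": _m(1.15, "dimensionless", 1.0, 2.0, "assumed"),
    "covid_employment_onset": _m(0.10, "dimensionless", 0.0, 1.0, "assumed"),
    "jobkeeper_damping": _m(0.5, "dimensionless", 0.0, 1.0, "assumed"),
}

_FRACTION_PARAMS = {
    name
    for name, meta in PARAM_META.items()
    if meta.unit.startswith("fraction") or name == "perceived_need"
}


class ParameterSet:
    """Immutable-ish bag of named model parameters with validation.

    Parameters are accessed as attributes (``params.remission``).  Use
    :meth:`replace` to derive a modified copy, :meth:`reference` for the
    shipped reference parameterisation, and :meth:`from_file` /
    :meth:`to_file` for the flat key-value text dialect
    (``name value unit lower upper source``, tab-separated).
    """

    __slots__ = ("_values", "_cache")

    def __init__(self, values: Mapping[str, float] | None = None, **overrides: float):
        vals = {name: meta.default for name, meta in PARAM_META.items()}
        for src in (values or {}), overrides:
            for name, v in src.items():
                if name not in PARAM_META:
                    raise KeyError(f"unknown parameter {name!r}")
                vals[name] = float(v)
        self._values = vals
        self._cache: dict = {}
        self._validate()

    def _validate(self) -> None:
        for name, v in self._values.items():
            if v < 0:
                raise ValueError(f"parameter {name!r} must be nonnegative, got {v}")
            if name in _FRACTION_PARAMS and not (0.0 <= v <= 1.0):
                raise ValueError(f"fraction parameter {name!r} outside [0, 1]: {v}")
        if self._values["sessions_per_user"] <= 0:
            raise ValueError("sessions_per_user must be positive")
        if self._values["capacity_2011"] <= 0:
            raise ValueError("capacity_2011 must be positive")

    def __getattr__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def __repr__(self) -> str:
        return f"ParameterSet({len(self._values)} parameters)"

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def replace(self, **overrides: float) -> "ParameterSet":
        return ParameterSet(self._values, **overrides)

    def initial_stocks(self):
        """Initial :class:`~mhsd.sd_core.StockVector` implied by the
        population/prevalence/occupancy parameters (delegated to the sector
        model, which owns the stock layout)."""
        from . import sector

        return sector.initial_stocks(self)

    # ------------------------------------------------------------------ I/O
    @staticmethod
    def calibrated_names() -> list[str]:
        """Parameters the calibrator frees by default (source=calibrated)."""
        return [n for n, m in PARAM_META.items() if m.source == "calibrated"]

    @staticmethod
    def bounds_for(names: Iterable[str]) -> list[tuple[float, float]]:
        return [(PARAM_META[n].lower, PARAM_META[n].upper) for n in names]

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tvalue\tunit\tlower\tupper\tsource\n")
            for name, v in self._values.items():
                meta = PARAM_META[name]
                fh.write(
                    f"{name}\t{v:.10g}\t{meta.unit}\t{meta.lower:.10g}\t"
                    f"{meta.upper:.10g}\t{meta.source}\n"
                )

    @classmethod
    def from_file(cls, path_or_buf) -> "ParameterSet":
        if hasattr(path_or_buf, "read"):
            lines = path_or_buf.read().splitlines()
        else:
            with open(path_or_buf) as fh:
                lines = fh.read().splitlines()
        values: dict[str, float] = {}
        for line in lines[1:]:
            if not line.strip():
                continue
            name, value = line.split("\t")[:2]
            values[name] = float(value)
        return cls(values)

    @classmethod
    def reference(cls) -> "ParameterSet":
        """The shipped reference parameterisation."""
        text = (
            resources.files("mhsd")
            .joinpath("data/reference_parameters.tsv")
            .read_text()
        )
        return cls.from_file(io.StringIO(text))
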