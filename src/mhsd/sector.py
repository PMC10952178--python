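"""The care-access sector model: distress dynamics, service pathways,
capacity-constrained specialist care, and adverse-outcome submodels.

The population is stratified by age band (0-14, 15-24, 25+) and by a
distress x care state:

``low``
    low psychological distress (K10 score below 16), not in care;
``dist``
    moderate-to-very-high distress (K10 16-50), not seeking care;
``wait``
    distressed, seeking care and waiting for a specialist appointment;
``gp``
    distressed, managed in GP care (assessed but not referred onward);
``spec``
    distressed, receiving subsidised specialist sessions (psychologists,
    psychiatrists, mental health allied professionals, pooled);
``diseng``
    distressed, disengaged from the care pathway after excessive waiting,
    carrying escalated adverse-outcome rates;
``recov``
    recently recovered through care, low distress.

Specialist capacity (sessions/year) grows linearly; a policy lever multiplies
the growth slope from a configured date.  Session demand — in-care treatment
plus queue admissions — is rationed proportionally when it exceeds capacity.
Waiting time follows Little's law on the capacity left after in-care demand,
and drives a piecewise-linear disengagement hazard above a reference wait.

Direct access reroutes a fraction of help-seekers straight into the
specialist queue, bypassing the GP pathway (and therefore also the
demand-filtering role of GP-absorbed care): whether that helps or harms is an
emergent race between the extra referral demand and the capacity slack
available to absorb it.
"""

from __future__ import annotations

import numpy as np

from .params import ParameterSet
from .sd_core import WEEKS_PER_YEAR, StockVector
from .scenarios import Scenario, modifier_at

__all__ = [
    "STATES",
    "BANDS",
    "STOCK_NAMES",
    "initial_stocks",
    "capacity_at",
    "waiting_time",
    "disengagement_rate",
    "pathway_split",
    "sessions_throughput",
    "outcome_rates",
    "prevalence_moderate_plus",
    "flow_field",
    "OBSERVABLES",
]

STATES = ("low", "dist", "wait", "gp", "spec", "diseng", "recov")
BANDS = ("0_14", "15_24", "25p")
STOCK_NAMES: tuple[str, ...] = tuple(
    f"{state}_{band}" for band in BANDS for state in STATES
)

_MODEL_START = 2011.0
_FREE_CAP_EPS = 1.0  # sessions/year guard against division by zero

# column indices within a (band, state) matrix
_LOW, _DIST, _WAIT, _GP, _SPEC, _DISENG, _RECOV = range(7)
# moderate-to-very-high distress states (K10 16-50)
_DISTRESSED_COLS = [_DIST, _WAIT, _GP, _SPEC, _DISENG]


def initial_stocks(p: ParameterSet) -> StockVector:
    """Initial stock vector at model start (2011.0), built from band
    populations, initial prevalences, and care-state occupancy fractions."""
    values = np.zeros((len(BANDS), len(STATES)))
    pops = (p.pop_0_14_2011, p.pop_15_24_2011, p.pop_25p_2011)
    prevs = (p.init_prev_0_14, p.init_prev_15_24, p.init_prev_25p)
    f_care = p.init_frac_waiting + p.init_frac_gp + p.init_frac_spec + p.init_frac_diseng
    if f_care > 1.0:
        raise ValueError("initial care-state fractions exceed the distressed pool")
    for b, (n, prev) in enumerate(zip(pops, prevs)):
        distressed = n * prev / 100.0
        low_pool = n - distressed
        values[b, _WAIT] = distressed * p.init_frac_waiting
        values[b, _GP] = distressed * p.init_frac_gp
        values[b, _SPEC] = distressed * p.init_frac_spec
        values[b, _DISENG] = distressed * p.init_frac_diseng
        values[b, _DIST] = distressed * (1.0 - f_care)
        values[b, _RECOV] = low_pool * p.init_frac_recov
        values[b, _LOW] = low_pool * (1.0 - p.init_frac_recov)
    return StockVector(STOCK_NAMES, values.ravel(), _MODEL_START)


def capacity_at(t: float, p: ParameterSet, scenario: Scenario) -> float:
    """Specialist session capacity (sessions/year) at time ``t``.

    Piecewise-linear: the baseline slope applies before the scenario's
    growth-acceleration start, slope x multiplier after, continuous at the
    switch.
    """
    if scenario.growth_multiplier < 1.0:
        raise ValueError("growth multiplier below 1 (deceleration) not modelled")
    c = p.capacity_2011 + p.capacity_slope * (t - _MODEL_START)
    if t > scenario.growth_start and scenario.growth_multiplier > 1.0:
        c += (scenario.growth_multiplier - 1.0) * p.capacity_slope * (
            t - scenario.growth_start
        )
    return c


def waiting_time(queue: float, p: ParameterSet, free_capacity: float) -> float:
    """Expected wait (weeks) for the queue to clear through free capacity.

    Little's-law throughput delay: W = queue * sessions-per-user /
    free-capacity, capped (default 104 weeks) so degenerate inputs saturate
    rather than blow up.
    """
    if queue <= 0.0:
        return 0.0
    w_years = queue * p.sessions_per_user / max(free_capacity, _FREE_CAP_EPS)
    return min(w_years * WEEKS_PER_YEAR, p.wait_cap)


def disengagement_rate(w_weeks: float, p: ParameterSet) -> float:
    """Hazard of abandoning the wait (per week): zero at or below the
    reference wait, linear in the relative excess above it."""
    excess = max(0.0, w_weeks - p.wait_ref)
    return p.disengage_coeff * excess / p.wait_ref


def pathway_split(
    seekers_flow: float, scenario: Scenario, t: float
) -> tuple[float, float]:
    """Split a help-seeking flow (persons/year) into (GP pathway, direct
    access).  Before the direct-access start date everyone enters via the GP;
    after it a fraction ``d`` books specialist care directly."""
    if seekers_flow < 0:
        raise ValueError("seekers_flow must be nonnegative")
    d = modifier_at(scenario, t).direct_access
    return seekers_flow * (1.0 - d), seekers_flow * d


def episode_sessions(p: ParameterSet, session_cap: float) -> float:
    """Mean subsidised sessions demanded per care episode under a given
    annual session cap, anchored at the observed 4.5 under the normal cap of
    10 and scaling sub-proportionally (few users reach the cap)."""
    return p.sessions_per_user * (session_cap / 10.0) ** p.cap_demand_elasticity


def sessions_throughput(
    in_care: float, p: ParameterSet, scenario: Scenario, t: float
) -> tuple[float, float]:
    """Care-completion flow (persons/year) and delivered sessions
    (sessions/year) for the in-care stock alone.

    Delivered sessions are the lesser of demand and capacity; the completion
    flow scales down proportionally when capacity-limited (people stay in
    care longer when their sessions are rationed).
    """
    if in_care <= 0.0:
        return 0.0, 0.0
    cap = modifier_at(scenario, t).session_cap
    sigma = episode_sessions(p, cap) * p.treatment_recovery  # sessions/person/year
    demand = sigma * in_care
    c = capacity_at(t, p, scenario)
    ration = min(1.0, c / demand) if demand > 0 else 1.0
    return ration * p.treatment_recovery * in_care, min(demand, c)


def _band_matrix(state: StockVector) -> np.ndarray:
    if state.names != STOCK_NAMES:
        raise ValueError("StockVector does not use the sector-model stock layout")
    return state.values.reshape(len(BANDS), len(STATES))


def _outcome_coeffs(p: ParameterSet) -> dict[str, np.ndarray]:
    return {
        "ed": np.array([p.ed_rate_0_14, p.ed_rate_15_24, p.ed_rate_25p]),
        "selfharm": np.array(
            [p.selfharm_rate_0_14, p.selfharm_rate_15_24, p.selfharm_rate_25p]
        ),
        "suicide": np.array(
            [p.suicide_rate_0_14, p.suicide_rate_15_24, p.suicide_rate_25p]
        ),
    }


def _person_equivalents(Y: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Per band: distressed persons weighted by care-state outcome
    multipliers (disengaged > waiting > not-seeking > GP > specialist)."""
    return (
        Y[:, _DIST]
        + p.outmult_waiting * Y[:, _WAIT]
        + p.outmult_gp * Y[:, _GP]
        + p.outmult_spec * Y[:, _SPEC]
        + p.diseng_escalation * Y[:, _DISENG]
    )


def outcome_rates(state: StockVector, p: ParameterSet) -> dict[str, float]:
    """Instantaneous adverse-outcome rates (events/week), for each outcome
    (ED presentations, self-harm hospitalisations, suicide deaths) and each
    reporting stratum (all ages, 15-24)."""
    Y = _band_matrix(state)
    equiv = _person_equivalents(Y, p)
    coeffs = _outcome_coeffs(p)
    out: dict[str, float] = {}
    for name, beta in coeffs.items():
        per_band = beta * equiv / WEEKS_PER_YEAR
        out[f"{name}_all"] = float(per_band.sum())
        out[f"{name}_15_24"] = float(per_band[1])
    return out


def prevalence_moderate_plus(state: StockVector, band: str = "all") -> float:
    """Percentage of the (band) population in moderate-to-very-high
    psychological distress (K10 16-50)."""
    Y = _band_matrix(state)
    if band == "all":
        rows = slice(None)
    elif band in BANDS:
        rows = BANDS.index(band)
    else:
        raise KeyError(f"unknown age band {band!r}")
    total = float(np.sum(Y[rows]))
    if total <= 0:
        raise ValueError(f"band {band!r} has no population")
    distressed = float(np.sum(Y[rows][..., _DISTRESSED_COLS]))
    return 100.0 * distressed / total


# --------------------------------------------------------------------------
# the flow field

_OUTCOME_NAMES = ("ed", "selfharm", "suicide")


def _compiled(p: ParameterSet) -> dict:
    """Per-parameter-set constant arrays, cached on the ParameterSet (the
    flow field is called ~10^3 times per run and ~10^5 times per fit)."""
    cache = p._cache
    arrays = cache.get("sector_arrays")
    if arrays is None:
        arrays = {
            "onset": np.array([p.onset_0_14, p.onset_15_24, p.onset_25p]),
            "ageing": np.array([p.ageing_0_14, p.ageing_15_24, 0.0]),
            "exit": np.array([p.exit_0_14, p.exit_15_24, p.exit_25p]),
            "beta": np.array(
                [
                    [p.ed_rate_0_14, p.ed_rate_15_24, p.ed_rate_25p],
                    [p.selfharm_rate_0_14, p.selfharm_rate_15_24, p.selfharm_rate_25p],
                    [p.suicide_rate_0_14, p.suicide_rate_15_24, p.suicide_rate_25p],
                ]
            ),
        }
        cache["sector_arrays"] = arrays
    return arrays


def flow_field(
    t: float, y: np.ndarray, p: ParameterSet, scenario: Scenario
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-stock net flows (per year) and auxiliary outputs at time ``t``.

    This is the single function handed to :func:`mhsd.sd_core.integrate`; it
    inlines the pathway operations for speed (they are unit-tested in their
    standalone forms above, which share the same formulas).
    """
    Y = y.reshape(len(BANDS), len(STATES))
    mods = modifier_at(scenario, t)

    L = Y[:, _LOW]
    D = Y[:, _DIST]
    Q = Y[:, _WAIT]
    G = Y[:, _GP]
    S = Y[:, _SPEC]
    X = Y[:, _DISENG]
    R = Y[:, _RECOV]

    arrays = _compiled(p)

    # distress onset: secular ramp (to the trend saturation year) x COVID shock
    trend = 1.0 + p.onset_trend * (min(t, p.onset_trend_end) - _MODEL_START)
    onset = arrays["onset"] * (max(trend, 0.0) * mods.onset_mult)
    f_onset = onset * L
    f_remit = p.remission * D

    # help seeking and the pathway split (secular uptake trend on top of the
    # perceived-need lever)
    lam = (
        p.perceived_need
        * mods.perceived_need_mult
        * p.help_seek_rate
        * (1.0 + p.seek_trend * (min(t, p.seek_trend_end) - _MODEL_START))
    )
    seekers = lam * D
    d = mods.direct_access
    gp_flow = seekers * (1.0 - d)
    to_queue = seekers * d + p.gp_referral_fraction * gp_flow
    to_gp_care = (1.0 - p.gp_referral_fraction) * gp_flow

    # specialist capacity, proportional rationing over in-care + admissions
    c = capacity_at(t, p, scenario)
    s_e = p.sessions_per_user * (mods.session_cap / 10.0) ** p.cap_demand_elasticity
    sigma = s_e * p.treatment_recovery
    q_tot = float(Q.sum())
    s_tot = float(S.sum())
    demand_incare = sigma * s_tot
    # queue intake (assessment/first-session workload) competes for the same
    # session capacity as in-care treatment
    demand_admit = p.intake_sessions * q_tot / p.admit_time
    total_demand = demand_incare + demand_admit
    phi = 1.0 if total_demand <= c else c / total_demand
    delivered = phi * total_demand

    # waiting time signal and disengagement hazard
    free_cap = max(c - demand_incare, _FREE_CAP_EPS)
    w_weeks = 0.0
    if q_tot > 0.0:
        w_weeks = min(q_tot * s_e / free_cap * WEEKS_PER_YEAR, p.wait_cap)
    hazard_year = (
        p.disengage_coeff
        * max(0.0, w_weeks - p.wait_ref)
        / p.wait_ref
        * WEEKS_PER_YEAR
    )

    f_admit = (phi / p.admit_time) * Q
    f_diseng = hazard_year * Q
    f_complete = (phi * p.treatment_recovery) * S
    f_gp_recov = p.gp_recovery * G
    f_gp_return = p.gp_return * G
    f_reengage = p.reengage_rate * X
    # disengaged people only rejoin the queue while waits are short; above
    # the reference wait they drift back to the untreated distressed pool
    reseek = p.reengage_seek_rate * max(0.0, 1.0 - w_weeks / p.wait_ref)
    f_reseek = reseek * X
    f_fade = p.recovery_fade * R

    flows = np.zeros_like(Y)
    flows[:, _LOW] = -f_onset + f_remit + f_fade
    flows[:, _DIST] = f_onset - f_remit - seekers + f_gp_return + f_reengage
    flows[:, _WAIT] = to_queue + f_reseek - f_admit - f_diseng
    flows[:, _GP] = to_gp_care - f_gp_recov - f_gp_return
    flows[:, _SPEC] = f_admit - f_complete
    flows[:, _DISENG] = f_diseng - f_reengage - f_reseek
    flows[:, _RECOV] = f_complete + f_gp_recov - f_fade

    # demography: entries, ageing (pure transfers), exits
    ageing = arrays["ageing"]
    exits = arrays["exit"]
    age_out = ageing[:, None] * Y
    flows -= age_out
    flows[1:] += age_out[:-1]
    flows -= exits[:, None] * Y
    flows[0, _LOW] += p.entry_children
    flows[2, _LOW] += p.entry_adults

    # auxiliaries
    pop = Y.sum(axis=1)
    distressed = Y[:, _DISTRESSED_COLS].sum(axis=1)
    equiv = _person_equivalents(Y, p)
    pop_total = pop.sum()
    aux: dict[str, float] = {
        "waiting_weeks": w_weeks,
        "prevalence_all": 100.0 * distressed.sum() / pop_total if pop_total else 0.0,
        "prevalence_15_24": 100.0 * distressed[1] / pop[1] if pop[1] else 0.0,
        "capacity": c,
        "delivered_sessions_week": delivered / WEEKS_PER_YEAR,
    }
    per_band = arrays["beta"] * (equiv / WEEKS_PER_YEAR)
    for i, name in enumerate(_OUTCOME_NAMES):
        aux[f"{name}_all"] = float(per_band[i].sum())
        aux[f"{name}_15_24"] = float(per_band[i, 1])
    return flows.ravel(), aux


# --------------------------------------------------------------------------
# observable outputs used for calibration and synthetic data

#: name -> ("annual_count", aux series) or ("level", aux series); annual
#: counts integrate the rate over the observation year, levels sample the
#: nearest grid point to the observation time.
OBSERVABLES: dict[str, tuple[str, str]] = {
    "ed_presentations": ("annual_count", "ed_all"),
    "selfharm_hospitalisations": ("annual_count", "selfharm_all"),
    "suicide_deaths": ("annual_count", "suicide_all"),
    "prevalence_moderate_plus": ("level", "prevalence_all"),
    "delivered_sessions": ("annual_count", "delivered_sessions_week"),
}
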