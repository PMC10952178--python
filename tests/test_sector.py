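"""Sector-model operations: capacity, queueing, pathways, outcomes."""

import numpy as np
import pytest

from mhsd.params import ParameterSet
from mhsd.scenarios import baseline, make_scenario
from mhsd.sd_core import WEEKS_PER_YEAR, StockVector, integrate
from mhsd import sector


@pytest.fixture(scope="module")
def params():
    return ParameterSet.reference()


@pytest.fixture(scope="module")
def base_scen(params):
    return baseline(params)


def _state(values: dict[str, float]) -> StockVector:
    arr = np.zeros(len(sector.STOCK_NAMES))
    for name, v in values.items():
        arr[sector.STOCK_NAMES.index(name)] = v
    return StockVector(sector.STOCK_NAMES, arr, 2020.0)


# ----------------------------------------------------------------- capacity
def test_capacity_linear_baseline(params, base_scen):
    c0 = sector.capacity_at(2011.0, params, base_scen)
    c7 = sector.capacity_at(2018.0, params, base_scen)
    assert c7 - c0 == pytest.approx(7 * params.capacity_slope, rel=1e-12)


def test_capacity_multiplier_from_t0():
    p = ParameterSet.reference().replace(capacity_2011=1000.0, capacity_slope=30.0)
    scen = make_scenario({"growth_multiplier": 2, "growth_start": 2011.0}, p)
    assert sector.capacity_at(2012.0, p, scen) == pytest.approx(1060.0)


def test_fivefold_growth_yields_71_6_percent_capacity_excess(params):
    """Fivefold slope from 1 Jan 2022 puts end-2028 capacity ~71.6% above
    the baseline projection."""
    scen5 = make_scenario({"growth_multiplier": 5}, params)
    base = baseline(params)
    t_end = 2029.0
    excess = sector.capacity_at(t_end, params, scen5) / sector.capacity_at(
        t_end, params, base
    ) - 1.0
    assert excess * 100 == pytest.approx(71.6, abs=0.1)


def test_capacity_rejects_deceleration(params):
    scen = baseline(params)
    object.__setattr__(scen, "growth_multiplier", 0.5)  # bypass scenario guard
    with pytest.raises(ValueError, match="multiplier"):
        sector.capacity_at(2020.0, params, scen)


# ------------------------------------------------------- waiting/disengaging
def test_waiting_time_littles_law(params):
    assert sector.waiting_time(0.0, params, 1000.0) == 0.0
    # 1000 queued * 4.5 sessions / 45 000 sessions/yr = 0.1 yr ~ 5.22 weeks
    w = sector.waiting_time(1000.0, params.replace(sessions_per_user=4.5), 45_000.0)
    assert w == pytest.approx(0.1 * WEEKS_PER_YEAR, rel=1e-9)
    assert w == pytest.approx(5.22, abs=0.01)


def test_waiting_time_saturates_at_cap(params):
    assert sector.waiting_time(500.0, params, 0.0) == params.wait_cap


def test_disengagement_hazard_piecewise_linear(params):
    p = params.replace(disengage_coeff=0.05, wait_ref=4.0)
    assert sector.disengagement_rate(4.0, p) == 0.0
    assert sector.disengagement_rate(0.0, p) == 0.0
    assert sector.disengagement_rate(8.0, p) == pytest.approx(0.05)


# ------------------------------------------------------------------ pathways
def test_pathway_split_examples(params):
    scen = make_scenario({"direct_access": 0.5, "direct_access_start": 2011.0}, params)
    gp, direct = sector.pathway_split(200.0, scen, 2020.0)
    assert (gp, direct) == (100.0, 100.0)
    # before the start date, everyone goes through the GP pathway
    gp, direct = sector.pathway_split(200.0, scen, 2010.99)
    assert (gp, direct) == (200.0, 0.0)
    gp, direct = sector.pathway_split(200.0, baseline(params), 2025.0)
    assert (gp, direct) == (200.0, 0.0)


def test_direct_access_amplifies_specialist_demand(params):
    """d=0.2 with referral fraction 0.6: queue inflow 68/yr vs 60/yr at d=0."""
    p = params.replace(gp_referral_fraction=0.6)
    scen = make_scenario({"direct_access": 0.2, "direct_access_start": 2011.0}, p)
    gp, direct = sector.pathway_split(100.0, scen, 2020.0)
    inflow = direct + p.gp_referral_fraction * gp
    assert inflow == pytest.approx(68.0)
    gp0, direct0 = sector.pathway_split(100.0, baseline(p), 2020.0)
    assert direct0 + p.gp_referral_fraction * gp0 == pytest.approx(60.0)
    assert inflow > 60.0


def test_pathway_split_rejects_negative_flow(params):
    with pytest.raises(ValueError):
        sector.pathway_split(-1.0, baseline(params), 2020.0)


# ---------------------------------------------------------------- throughput
def test_sessions_throughput_regimes(params, base_scen):
    t = 2015.0
    cap = sector.capacity_at(t, params, base_scen)
    sigma = sector.episode_sessions(params, 10.0) * params.treatment_recovery
    # unconstrained: completion = in_care * recovery rate, delivered = demand
    small = cap / sigma * 0.1
    completion, delivered = sector.sessions_throughput(small, params, base_scen, t)
    assert completion == pytest.approx(small * params.treatment_recovery)
    assert delivered == pytest.approx(sigma * small)
    # demand at twice capacity: delivered = capacity, completion halved
    big = 2.0 * cap / sigma
    completion2, delivered2 = sector.sessions_throughput(big, params, base_scen, t)
    assert delivered2 == pytest.approx(cap)
    assert completion2 == pytest.approx(0.5 * big * params.treatment_recovery)
    assert sector.sessions_throughput(0.0, params, base_scen, t) == (0.0, 0.0)


# ------------------------------------------------------------------ outcomes
def test_outcome_rates_zero_without_distress(params):
    state = _state({"low_0_14": 1e6, "low_25p": 4e6, "recov_15_24": 1e5})
    rates = sector.outcome_rates(state, params)
    assert all(v == 0.0 for v in rates.values())


def test_outcome_rate_unit_conversion(params):
    p = params.replace(suicide_rate_25p=1e-3)
    state = _state({"dist_25p": 1000.0})
    rates = sector.outcome_rates(state, p)
    assert rates["suicide_all"] == pytest.approx(1.0 / WEEKS_PER_YEAR, rel=1e-12)
    assert rates["suicide_all"] == pytest.approx(0.0192, abs=2e-4)


def test_disengagement_strictly_raises_all_outcomes(params):
    in_care = _state({"spec_15_24": 500.0, "dist_15_24": 1000.0})
    shifted = _state({"spec_15_24": 400.0, "diseng_15_24": 100.0, "dist_15_24": 1000.0})
    before = sector.outcome_rates(in_care, params)
    after = sector.outcome_rates(shifted, params)
    for key in before:
        if key.endswith("_all"):
            assert after[key] > before[key]


def test_outcome_multiplier_ordering(params):
    assert (
        params.diseng_escalation
        > params.outmult_waiting
        > params.outmult_gp
        > params.outmult_spec
    )


# ---------------------------------------------------------------- prevalence
def test_prevalence_examples(params):
    assert sector.prevalence_moderate_plus(_state({"low_25p": 1000.0})) == 0.0
    mixed = _state({"low_25p": 700.0, "dist_25p": 200.0, "wait_25p": 100.0})
    assert sector.prevalence_moderate_plus(mixed) == pytest.approx(30.0)
    assert sector.prevalence_moderate_plus(mixed, "25p") == pytest.approx(30.0)
    with pytest.raises(ValueError, match="population"):
        sector.prevalence_moderate_plus(_state({"low_25p": 10.0}), "15_24")
    with pytest.raises(KeyError):
        sector.prevalence_moderate_plus(mixed, "30_40")


def test_reference_run_reproduces_2019_prevalence(baseline_traj):
    """Calibration era: ~43.5% of the population in moderate-to-very-high
    distress in 2019 (within calibration tolerance)."""
    prev_2019 = baseline_traj.aux_at("prevalence_all", 2019.5)
    assert prev_2019 == pytest.approx(43.5, abs=2.5)


# ------------------------------------------------------------- whole-system
def test_closed_demography_conserves_population(params, base_scen):
    closed = params.replace(
        entry_children=0.0, entry_adults=0.0, exit_0_14=0.0, exit_15_24=0.0, exit_25p=0.0
    )
    traj = integrate(sector.flow_field, closed, base_scen, 2011.0, 2028.0, 1 / 52)
    totals = traj.stocks.sum(axis=1)
    assert np.all(np.abs(totals / totals[0] - 1.0) < 1e-9)


def test_delivered_sessions_never_exceed_capacity(baseline_traj):
    delivered = baseline_traj.aux["delivered_sessions_week"] * WEEKS_PER_YEAR
    assert np.all(delivered <= baseline_traj.aux["capacity"] * (1 + 1e-12))


def test_event_rate_series_nonnegative(baseline_traj):
    for name in ("ed_all", "selfharm_all", "suicide_all",
                 "ed_15_24", "selfharm_15_24", "suicide_15_24"):
        assert np.all(baseline_traj.aux[name] >= 0)


def test_monotonic_mechanism_chain(params, base_scen):
    """One step, ceteris paribus: more queued -> longer wait -> higher
    disengagement hazard -> higher outcome rates."""
    t = 2025.0
    base = _state({"dist_25p": 1e6, "wait_25p": 5e4, "spec_25p": 1e5})
    more = _state({"dist_25p": 1e6, "wait_25p": 8e4, "spec_25p": 1e5})
    flows_b, aux_b = sector.flow_field(t, base.values, params, base_scen)
    flows_m, aux_m = sector.flow_field(t, more.values, params, base_scen)
    assert aux_m["waiting_weeks"] > aux_b["waiting_weeks"]
    h_b = sector.disengagement_rate(aux_b["waiting_weeks"], params)
    h_m = sector.disengagement_rate(aux_m["waiting_weeks"], params)
    assert h_m > h_b
    for key in ("ed_all", "selfharm_all", "suicide_all"):
        assert aux_m[key] > aux_b[key]


def test_initial_stocks_layout(params):
    init = params.initial_stocks()
    assert init.names == sector.STOCK_NAMES
    assert np.all(init.values >= 0)
    total = init.total()
    assert total == pytest.approx(
        params.pop_0_14_2011 + params.pop_15_24_2011 + params.pop_25p_2011
    )
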