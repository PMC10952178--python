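"""Integration engine: closed-form oracles, conservation, cumulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhsd.sd_core import (
    WEEKS_PER_YEAR,
    NonFiniteFlowError,
    StockVector,
    cumulate,
    decimal_year,
    integrate,
)


def test_decimal_year_convention():
    assert decimal_year(2021, 9, 1) == pytest.approx(2021.6653, abs=5e-5)
    assert decimal_year(2022, 1, 1) == 2022.0
    # leap year shifts day-of-year by one
    assert decimal_year(2028, 9, 1) == pytest.approx(2028.6680, abs=5e-5)


def test_zero_flows_keep_stocks_constant(toy_params):
    p = toy_params(("a", "b"), (3.0, 7.5))
    traj = integrate(lambda t, y, pp, s: (np.zeros_like(y), None), p, None, 0, 2, 1 / 52)
    assert np.all(traj.stocks == [3.0, 7.5])


def test_exponential_decay_matches_closed_form(toy_params):
    p = toy_params(("x",), (100.0,))
    field = lambda t, y, pp, s: (-0.5 * y, None)
    traj = integrate(field, p, None, 0, 2, 1 / 52)
    exact = 100.0 * np.exp(-1.0)
    assert traj.stocks[-1, 0] == pytest.approx(exact, rel=0.005)
    # forward Euler is first order: halving dt at least halves the error
    err = abs(integrate(field, p, None, 0, 2, 1 / 52).stocks[-1, 0] - exact)
    err_half = abs(integrate(field, p, None, 0, 2, 1 / 104).stocks[-1, 0] - exact)
    assert err_half <= 0.6 * err


def test_constant_inflow_is_exact(toy_params):
    p = toy_params(("x",), (0.0,))
    traj = integrate(lambda t, y, pp, s: (np.full(1, 10.0), None), p, None, 0, 3, 1 / 52)
    assert traj.stocks[-1, 0] == pytest.approx(30.0, abs=1e-9)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_pure_transfers_conserve_total(seed):
    """A closed subsystem whose flows are pure transfers keeps its total."""
    rng = np.random.default_rng(seed)
    n = 4
    rates = rng.uniform(0, 2, size=(n, n))
    np.fill_diagonal(rates, 0.0)
    init = rng.uniform(10, 100, size=n)

    def field(t, y, pp, s):
        moved = rates * y[:, None]  # moved[i, j]: flow i -> j
        return moved.sum(axis=0) - moved.sum(axis=1), None

    class P:
        def initial_stocks(self):
            return StockVector(tuple("abcd"), init.copy(), 0.0)

    traj = integrate(field, P(), None, 0.0, 5.0, 1 / 52)
    totals = traj.stocks.sum(axis=1)
    assert np.all(np.abs(totals / totals[0] - 1.0) < 1e-9)


def test_linear_field_error_halves_with_dt(toy_params):
    """First-order convergence against the matrix-exponential solution."""
    from scipy.linalg import expm

    A = np.array([[-1.2, 0.3], [0.9, -0.7]])
    init = np.array([50.0, 10.0])
    p = toy_params(("u", "v"), init)
    field = lambda t, y, pp, s: (A @ y, None)
    exact = expm(2.0 * A) @ init

    def max_rel_err(dt):
        end = integrate(field, p, None, 0, 2, dt).stocks[-1]
        return np.max(np.abs(end - exact) / np.abs(exact))

    assert max_rel_err(1 / 104) <= 0.55 * max_rel_err(1 / 52)


def test_integrate_rejects_bad_grid(toy_params):
    p = toy_params(("x",), (1.0,))
    field = lambda t, y, pp, s: (np.zeros(1), None)
    with pytest.raises(ValueError, match="exceeds the span"):
        integrate(field, p, None, 0, 1, dt=2.0)
    with pytest.raises(ValueError):
        integrate(field, p, None, 1.0, 1.0, 1 / 52)


def test_non_finite_flow_aborts_with_context(toy_params):
    p = toy_params(("good", "bad"), (1.0, 1.0))

    def field(t, y, pp, s):
        return np.array([0.0, np.nan if t > 0.5 else 0.0]), None

    with pytest.raises(NonFiniteFlowError) as err:
        integrate(field, p, None, 0, 1, 1 / 52)
    assert err.value.stock == "bad"
    assert err.value.time > 0.5


def test_negative_overshoot_clamped_and_logged(toy_params):
    p = toy_params(("x",), (1.0,))
    traj = integrate(lambda t, y, pp, s: (np.full(1, -60.0), None), p, None, 0, 1, 1 / 52)
    assert np.all(traj.stocks >= 0)
    assert traj.clamped["x"] > 0


def _rate_traj(rate_fn, t0=0.0, t1=4.0, dt=1 / 52):
    n = int(round((t1 - t0) / dt))
    times = t0 + dt * np.arange(n + 1)
    from mhsd.sd_core import Trajectory

    return Trajectory(
        times, ("x",), np.zeros((n + 1, 1)), aux={"r": rate_fn(times)}
    )


def test_cumulate_constant_rate_analytic():
    traj = _rate_traj(lambda t: np.full_like(t, 100.0))
    expected = 100.0 * 2 * 365.25 / 7  # ~10 435.7 events
    assert cumulate(traj, "r", (1.0, 3.0)) == pytest.approx(expected, rel=1e-12)


def test_cumulate_degenerate_windows():
    traj = _rate_traj(lambda t: np.full_like(t, 100.0))
    assert cumulate(traj, "r", (1.5, 1.5)) == 0.0
    zero = _rate_traj(np.zeros_like)
    assert cumulate(zero, "r", (0.0, 4.0)) == 0.0


def test_cumulate_additive_over_adjacent_windows():
    traj = _rate_traj(lambda t: 10.0 + 3.0 * np.sin(t))
    whole = cumulate(traj, "r", (0.3, 3.7))
    split = cumulate(traj, "r", (0.3, 1.234)) + cumulate(traj, "r", (1.234, 3.7))
    assert whole == pytest.approx(split, rel=1e-12)


def test_cumulate_rejects_window_outside_span():
    traj = _rate_traj(lambda t: np.full_like(t, 1.0))
    with pytest.raises(ValueError, match="span"):
        cumulate(traj, "r", (3.0, 5.0))
    with pytest.raises(KeyError):
        cumulate(traj, "nope", (0.0, 1.0))


def test_trajectory_frame_and_export(tmp_path, toy_params):
    p = toy_params(("x",), (2.0,))
    traj = integrate(
        lambda t, y, pp, s: (np.zeros(1), {"aux1": float(t)}), p, None, 0, 1, 1 / 52
    )
    frame = traj.to_frame()
    assert list(frame.columns) == ["time", "x", "aux1"]
    out = tmp_path / "traj.csv"
    traj.to_csv(out)
    assert out.read_text().startswith("time,x,aux1")
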