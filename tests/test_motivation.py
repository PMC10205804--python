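"""Closed-form motivational dynamics against direct computation and Euler."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corvidsim.motivation import (
    MotivationParameters,
    MotivationState,
    gated_time_above,
    hunger_crossing_times,
    on_cache,
    on_eat,
    propagate,
)
from oracles import euler_motivation


def one_food_state(s, h, c=1.0):
    return MotivationState(s={"worm": s}, h={"worm": h}, c={"worm": c})


def test_hunger_fixed_point_at_one(mparams):
    st_ = one_food_state(0.0, 1.0)
    propagate(st_, 500.0, mparams)
    assert st_.h["worm"] == pytest.approx(1.0)


def test_stomach_empties_linearly(mparams):
    st_ = one_food_state(0.5, 0.9)
    propagate(st_, 1.0, mparams)
    assert st_.s["worm"] == pytest.approx(0.5 - 1.0 / 5.0)
    st_ = one_food_state(0.5, 0.9)
    propagate(st_, 2.5, mparams)  # t* = 0.5 * tau_s = 2.5 min exactly
    assert st_.s["worm"] == pytest.approx(0.0)


def test_hunger_two_phase_closed_form():
    # s=1, tau_s=5 -> stomach empty at 5 min; decay 5 min, relax 15 min
    p = MotivationParameters(tau_s=5.0, tau_d=10.0, tau_h=100.0, n={"worm": 0.5})
    st_ = one_food_state(1.0, 0.8)
    propagate(st_, 20.0, p)
    h5 = 0.8 * math.exp(-5.0 / 10.0)
    expected = 1.0 - (1.0 - h5) * math.exp(-15.0 / 100.0)
    assert st_.h["worm"] == pytest.approx(expected, abs=1e-12)
    # and against the independent Euler oracle at dt = 0.01 min
    _, h_e, _ = euler_motivation(
        [1.0], [0.8], [1.0], [5.0], [10.0], [100.0], [0.5],
        [], [], [], 20.0, 0.01, [20.0])
    assert st_.h["worm"] == pytest.approx(h_e[0, 0], abs=1e-4)


def test_on_eat_specific_satiety(mparams, mstate):
    on_eat(mstate, "worm", mparams)
    on_eat(mstate, "worm", mparams)
    assert mstate.s["worm"] == pytest.approx(1.0)
    assert mstate.s["peanut"] == 0.0
    with pytest.raises(ValueError):
        on_eat(mstate, "stone", mparams)


def test_on_cache_depletion_and_recovery():
    p = MotivationParameters(tau_d=2.0, c0=1.0, n={"worm": 0.5})
    st_ = one_food_state(0.0, 1.0, c=1.0)
    on_cache(st_, "worm", p)
    assert st_.c["worm"] == pytest.approx(0.5)  # c - c*c0/tau_d = 1 - 0.5
    # with c0 = 0 caching leaves the drive unchanged
    p0 = MotivationParameters(tau_d=2.0, c0=0.0, n={"worm": 0.5})
    st0 = one_food_state(0.0, 1.0, c=0.8)
    on_cache(st0, "worm", p0)
    assert st0.c["worm"] == pytest.approx(0.8)
    # repeated caching drives c to 0; without caching it relaxes back to 1
    for _ in range(50):
        on_cache(st_, "worm", p)
    assert st_.c["worm"] < 1e-6
    propagate(st_, 2.0, p)
    assert st_.c["worm"] == pytest.approx(1.0 - math.exp(-1.0))


def test_maintenance_diet_integrates_as_fed(mparams):
    st_ = one_food_state(0.0, 0.9)
    propagate(st_, 10.0, mparams, maintenance_diet=True)
    assert st_.h["worm"] == pytest.approx(0.9 * math.exp(-1.0))


def test_negative_dt_rejected(mparams, mstate):
    with pytest.raises(ValueError):
        propagate(mstate, -1.0, mparams)


def test_crossing_time_upward():
    p = MotivationParameters(tau_s=5.0, tau_d=10.0, tau_h=100.0, n={"worm": 0.5})
    st_ = one_food_state(0.0, 0.5)
    cr = hunger_crossing_times(st_, 1000.0, 0.99, p)["worm"]
    expected = -100.0 * math.log((1 - 0.99) / (1 - 0.5))
    assert cr == [(pytest.approx(expected), +1)]
    # saturated hunger never crosses downward without food
    st1 = one_food_state(0.0, 1.0)
    assert hunger_crossing_times(st1, 1000.0, 0.99, p)["worm"] == []


def test_crossing_time_downward_while_digesting():
    p = MotivationParameters(tau_s=5.0, tau_d=10.0, tau_h=100.0, n={"worm": 0.5})
    st_ = one_food_state(2.0, 1.0)  # stomach empties at 10 min
    cr = hunger_crossing_times(st_, 10.0, 0.99, p)["worm"]
    expected = 10.0 * math.log(1.0 / 0.99)
    assert cr == [(pytest.approx(expected), -1)]
    # gated time above theta equals the crossing time here
    gt = gated_time_above(st_, 10.0, 0.99, p)["worm"]
    assert gt == pytest.approx(expected)


@settings(max_examples=60, derandomize=True)
@given(
    s0=st.floats(0.0, 3.0),
    h0=st.floats(0.0, 1.0),
    dt1=st.floats(0.0, 100.0),
    dt2=st.floats(0.0, 100.0),
    tau_d=st.floats(1.0, 20.0),
)
def test_semigroup_property(s0, h0, dt1, dt2, tau_d):
    """propagate(dt1) then propagate(dt2) equals propagate(dt1 + dt2)."""
    p = MotivationParameters(tau_s=5.0, tau_d=tau_d, tau_h=100.0, n={"worm": 0.5})
    a = one_food_state(s0, h0, 0.3)
    propagate(a, dt1, p)
    propagate(a, dt2, p)
    b = one_food_state(s0, h0, 0.3)
    propagate(b, dt1 + dt2, p)
    for var in ("s", "h", "c"):
        assert getattr(a, var)["worm"] == pytest.approx(
            getattr(b, var)["worm"], abs=1e-10)


@settings(max_examples=60, derandomize=True)
@given(seed=st.integers(0, 10 ** 6))
def test_bounds_after_event_sequences(seed):
    rng = random.Random(seed)
    p = MotivationParameters(
        tau_s=rng.uniform(0.5, 10), tau_d=rng.uniform(0.0, 20),
        tau_h=rng.uniform(50, 300), n={"worm": rng.uniform(0.1, 1)},
        c0=rng.uniform(0, 1))
    st_ = one_food_state(0.0, rng.random())
    for _ in range(30):
        ev = rng.random()
        if ev < 0.4:
            on_eat(st_, "worm", p)
        elif ev < 0.6:
            on_cache(st_, "worm", p)
        else:
            propagate(st_, rng.uniform(0, 200), p)
        assert st_.s["worm"] >= 0.0
        assert 0.0 <= st_.h["worm"] <= 1.0
        assert 0.0 <= st_.c["worm"] <= 1.0


def test_closed_form_matches_euler_small_batch():
    """Spot check of the full oracle-equivalence harness at small n."""
    rng = np.random.default_rng(7)
    n = 20
    tau_s = rng.uniform(0.5, 10, n)
    tau_d = rng.uniform(3.0, 20, n)
    tau_h = rng.uniform(50, 300, n)
    nval = rng.uniform(0.1, 1, n)
    c0p = rng.uniform(0, 1, n)
    t_end, dt = 300.0, 0.01
    events = sorted((round(rng.uniform(1, t_end - 1), 2), i)
                    for i in range(n) for _ in range(3))
    amounts = [nval[i] for _, i in events]
    checkpoints = [75.0, 150.0, 299.99]
    s_e, h_e, c_e = euler_motivation(
        np.zeros(n), np.full(n, 0.9), np.ones(n), tau_s, tau_d, tau_h, c0p,
        events, amounts, [], t_end, dt, checkpoints)
    for i in range(n):
        p = MotivationParameters(tau_s[i], tau_d[i], tau_h[i],
                                 {"worm": nval[i]}, c0p[i])
        st_ = one_food_state(0.0, 0.9)
        t_prev = 0.0
        marks = sorted([(t, "eat") for t, j in events if j == i]
                       + [(t, "cp") for t in checkpoints])
        results = []
        for t, kind in marks:
            propagate(st_, t - t_prev, p)
            t_prev = t
            if kind == "eat":
                on_eat(st_, "worm", p)
            else:
                results.append((st_.s["worm"], st_.h["worm"], st_.c["worm"]))
        for j, (s_cf, h_cf, c_cf) in enumerate(results):
            assert abs(s_cf - s_e[j, i]) < 1e-3
            assert abs(h_cf - h_e[j, i]) < 1e-3
            assert abs(c_cf - c_e[j, i]) < 1e-3
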