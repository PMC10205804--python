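"""Continuous-time motivational control: per-food stomach, hunger and caching drive.

Each food type f has a stomach variable s_f >= 0 and a hunger variable
h_f in [0, 1].  The stomach empties linearly at rate 1/tau_s while s_f > 0;
eating an item of type f adds its nutritional value n_f instantaneously.
While the stomach holds food, hunger decays exponentially with the digestion
time constant tau_d; once the stomach is empty, hunger relaxes back towards 1
with the (much slower) appetite time constant tau_h:

    ds_f/dt = -[s_f > 0] / tau_s   (+ n_f at eating events)
    dh_f/dt = -h_f / tau_d [s_f > 0] + (1 - h_f) / tau_h [s_f = 0]

"Zero" stomach is a behavioral zero: the emptiness level at which the hunger
feeling starts to rise again.  The optional caching-drive variables c_f
(used by the caching-modulated policy variant) relax towards 1 with time
constant tau_d and drop multiplicatively at each caching event.

All dynamics between events are solved in closed form; the only
nondifferentiable point inside an interval, the stomach-empty time
t* = s_f * tau_s, is handled exactly.  Times are in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class MotivationParameters:
    tau_s: float = 5.0  # stomach time constant [0.5, 10] min
    tau_d: float = 10.0  # digestion time constant [0, 20] min
    tau_h: float = 150.0  # appetite increase time constant [50, 300] min
    n: dict[str, float] = field(default_factory=dict)  # nutritional value [0.1, 1]
    c0: float = 0.5  # caching-drive depletion [0, 1]


@dataclass
class MotivationState:
    s: dict[str, float]
    h: dict[str, float]
    c: dict[str, float]
    last_update: float = 0.0

    @classmethod
    def initial(cls, food_types, h0: float = 1.0, t: float = 0.0) -> "MotivationState":
        return cls(
            s={f: 0.0 for f in food_types},
            h={f: h0 for f in food_types},
            c={f: 1.0 for f in food_types},
            last_update=t,
        )


def _propagate_food(s: float, h: float, dt: float, p: MotivationParameters,
                    assume_fed: bool) -> tuple[float, float]:
    """Closed-form update of one (s, h) pair over dt minutes."""
    if assume_fed:
        # maintenance diet: integrate as if s_f > 0 throughout
        h = h * _exp_decay(dt, p.tau_d)
        return s, h
    if s > 0.0:
        t_star = s * p.tau_s  # stomach-empty time
        if dt <= t_star:
            return s - dt / p.tau_s, h * _exp_decay(dt, p.tau_d)
        h = h * _exp_decay(t_star, p.tau_d)
        rest = dt - t_star
        return 0.0, 1.0 - (1.0 - h) * math.exp(-rest / p.tau_h)
    return 0.0, 1.0 - (1.0 - h) * math.exp(-dt / p.tau_h)


def _exp_decay(dt: float, tau: float) -> float:
    # tau_d may be 0 (instantaneous digestion-driven satiation)
    if tau <= 0.0:
        return 0.0 if dt > 0.0 else 1.0
    return math.exp(-dt / tau)


def propagate(state: MotivationState, dt: float, params: MotivationParameters,
              maintenance_diet: bool = False) -> MotivationState:
    """Advance all motivational variables by dt minutes (no events inside)."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return state
    for f in state.s:
        state.s[f], state.h[f] = _propagate_food(
            state.s[f], state.h[f], dt, params, maintenance_diet
        )
        state.c[f] = 1.0 - (1.0 - state.c[f]) * _exp_decay(dt, params.tau_d)
    state.last_update += dt
    return state


def on_eat(state: MotivationState, food_type: str, params: MotivationParameters) -> MotivationState:
    """Instantaneous stomach increase by the nutritional value n_f."""
    try:
        n_f = params.n[food_type]
    except KeyError:
        raise ValueError(f"no nutritional value for {food_type!r} (not eatable?)") from None
    state.s[food_type] += n_f
    return state


def on_cache(state: MotivationState, food_type: str, params: MotivationParameters) -> MotivationState:
    """Caching-drive depletion: c_f drops by c_f * c0 / tau_d (floored at 0)."""
    if params.tau_d <= 0.0:
        state.c[food_type] = 0.0
        return state
    c = state.c[food_type]
    state.c[food_type] = max(0.0, c - c * params.c0 / params.tau_d)
    return state


def hunger_crossing_times(state: MotivationState, dt: float, theta: float,
                          params: MotivationParameters,
                          maintenance_diet: bool = False) -> dict[str, list[tuple[float, int]]]:
    """Exact times in (0, dt] at which each h_f crosses theta.

    Returns per food a list of (time, direction) with direction +1 for an
    upward and -1 for a downward crossing.  Needed to integrate hunger-gated
    weight growth exactly: the gate is open exactly while h_f > theta.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must be in (0, 1)")
    out: dict[str, list[tuple[float, int]]] = {}
    for f in state.h:
        crossings: list[tuple[float, int]] = []
        h = state.h[f]
        s = state.s[f]
        t0 = 0.0
        if maintenance_diet or s > 0.0:
            t_star = math.inf if maintenance_diet else s * params.tau_s
            # decaying phase: downward crossing possible
            if h > theta:
                if params.tau_d <= 0.0:
                    t_cross = 0.0
                else:
                    t_cross = params.tau_d * math.log(h / theta)
                if t_cross <= min(dt, t_star):
                    crossings.append((t_cross, -1))
            if t_star >= dt:
                out[f] = crossings
                continue
            h = h * _exp_decay(t_star, params.tau_d)
            t0 = t_star
        # relaxation towards 1: upward crossing possible
        if h < theta:
            t_cross = t0 + params.tau_h * math.log((1.0 - h) / (1.0 - theta))
            if t_cross <= dt:
                crossings.append((t_cross, +1))
        out[f] = crossings
    return out


def trajectory_rows(state: MotivationState, dt: float, step: float,
                    params: MotivationParameters,
                    maintenance_diet: bool = False) -> list[tuple]:
    """Sampled (time, food_type, s, h, c) rows over [0, dt] for plotting.

    Propagates a copy of the state on a fixed grid; write with
    ``csv.writer`` or ``pandas.DataFrame(rows, columns=...)``.
    """
    work = MotivationState(s=dict(state.s), h=dict(state.h), c=dict(state.c),
                           last_update=state.last_update)
    rows = []
    n_steps = int(dt / step)
    for k in range(n_steps + 1):
        t = k * step
        for f in work.s:
            rows.append((round(t, 6), f, work.s[f], work.h[f], work.c[f]))
        if k < n_steps:
            propagate(work, step, params, maintenance_diet)
    return rows


def gated_time_above(state: MotivationState, dt: float, theta: float,
                     params: MotivationParameters,
                     maintenance_diet: bool = False) -> dict[str, float]:
    """Accumulated time within [0, dt] during which h_f > theta, per food."""
    crossings = hunger_crossing_times(state, dt, theta, params, maintenance_diet)
    out = {}
    for f, cr in crossings.items():
        above = state.h[f] > theta
        t_prev = 0.0
        total = 0.0
        for t, direction in sorted(cr):
            if above:
                total += t - t_prev
            above = direction > 0
            t_prev = t
        if above:
            total += dt - t_prev
        out[f] = total
    return out
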