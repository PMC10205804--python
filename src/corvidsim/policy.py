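"""Action preferences and the rejection-sampling attention loop.

At any instant a bird has 1 + n_f + n_f*n_x + n_x candidate actions: doing
something unrelated ("other"), eating one of the n_f available food types,
caching any food type in any of the n_x open trays, or inspecting a tray.
Preferences are clipped-linear functions of hunger, caching weights and
memory recall:

    p_eat(f)      = sigma(v_eat_f h_f + eta_eat)
    p_cache(f,x)  = sigma(w_cache_{f,x_p} + w_cache_{f,x_a} + v_cache_f h_f + eta_cache)
    p_inspect(x)  = max_{f,l} sigma(phi^(l)_f v^(l)_f + v_inspect_f h_f + eta_inspect)

with sigma(u) = min(1, max(0, u)) and v_inspect_f = s_inspect * v_eat_f.
Policy variants swap the hunger term of p_cache (dropped, or replaced by the
caching drive c_f) and the planning-by-replay model replaces the two caching
weight terms by tanh of its replayed weight.

Selection emulates an attention mechanism: attend to a uniformly random
candidate, accept it if its preference exceeds a fresh uniform threshold,
else re-attend.  The induced distribution is proportional to preferences.
After each action the bird idles for u ~ U[1, delta_kind] seconds.
"""

from __future__ import annotations

from dataclasses import dataclass


def sigma(u: float) -> float:
    """Clipped-linear activation to [0, 1]."""
    return 0.0 if u < 0.0 else (1.0 if u > 1.0 else u)


@dataclass
class ActionCandidate:
    kind: str  # "eat" | "cache" | "retrieve" | "other"
    food_type: str | None
    tray: int | None  # tray appearance
    preference: float


def eat_preference(v_eat_f: float, h_f: float, eta_eat: float,
                   perceived: bool = True) -> float:
    """Preference of eating a perceived item of food type f.

    Remembered-only food (perceived=False) cannot be eaten: the food
    indicator term forces the preference to zero.
    """
    if not perceived:
        return 0.0
    return sigma(v_eat_f * h_f + eta_eat)


def cache_preference(w_xp: float, w_xa: float, v_cache_f: float,
                     drive: float, eta_cache: float,
                     variant: str = "hunger_modulated",
                     replay_weight: float | None = None) -> float:
    """Preference of caching food f in an open tray with feature weights w_xp, w_xa.

    ``drive`` is h_f for the hunger-modulated variant and c_f for the
    caching-modulated variant; the unmodulated variant ignores it.  If
    ``replay_weight`` is given (planning-by-replay), tanh of that weight
    replaces the two feature-weight terms (pass the already-squashed value).
    """
    w_term = replay_weight if replay_weight is not None else (w_xp + w_xa)
    if variant == "hunger_modulated":
        mod = v_cache_f * drive
    elif variant == "caching_modulated":
        mod = v_cache_f * drive
    elif variant == "unmodulated":
        mod = 0.0
    else:
        raise ValueError(f"unknown caching variant {variant!r}")
    return sigma(w_term + mod + eta_cache)


def inspect_preference(recall_acts, readout, v_inspect: dict[str, float],
                       h: dict[str, float], eta_inspect: float) -> float:
    """max over (f, l) of sigma(phi^(l)_f v^(l)_f + v_inspect_f h_f + eta_inspect).

    ``recall_acts`` maps (layer, food) -> activation for the perceived tray;
    ``readout(layer, food)`` returns v^(l)_f.  Food types with no recalled
    trace still enter the max with phi = 0.
    """
    best = 0.0
    for f in h:
        base = v_inspect[f] * h[f] + eta_inspect
        p = sigma(base)
        if p > best:
            best = p
    for (layer, food), act in recall_acts.items():
        if food not in h:
            continue
        p = sigma(act * readout(layer, food) + v_inspect[food] * h[food] + eta_inspect)
        if p > best:
            best = p
    return best


def select_action(candidates: list[ActionCandidate], rng,
                  max_rounds_per_candidate: int = 10) -> tuple[ActionCandidate, int]:
    """Rejection-sampling selection; returns (candidate, iterations used).

    If every preference is zero the loop cannot terminate; after a bounded
    number of rounds the "other" candidate (or the first one) is forced and
    the returned iteration count is negative to flag the degenerate draw.
    """
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    n = len(candidates)
    cap = max_rounds_per_candidate * n
    for it in range(1, cap + 1):
        cand = candidates[int(rng.random() * n)]
        if cand.preference > rng.random():
            return cand, it
    fallback = next((c for c in candidates if c.kind == "other"), candidates[0])
    return fallback, -cap


def draw_timeout_seconds(kind: str, params, rng) -> float:
    """Post-action idle time u ~ U[1, delta_kind] in seconds."""
    delta = {
        "eat": params.delta_eat,
        "cache": params.delta_cache,
        "retrieve": params.delta_inspect,
        "other": params.delta_other,
    }[kind]
    return 1.0 + (delta - 1.0) * rng.random()
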