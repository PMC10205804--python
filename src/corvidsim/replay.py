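"""Planning-by-replay: an episodic buffer of tray-hunger-outcome episodes.

The control model for the mental-time-travel hypothesis.  Interactions with
caching trays are grouped into memory items: consecutive interactions less
than one hour apart share one item, a longer gap opens a new item.  Each
item is a list of (tray, hunger-vector, outcome) triples with outcome in
{pilfered, fresh_food_item, degraded_food_item, not_inspected}.

Before caching, the buffer is queried with the current context (the tray
sequences of the last three items); the best-matching earlier positions are
replayed forward for up to six items, and replayed retrieval outcomes at the
candidate tray are combined into a signed caching weight

    w_fx = sum_{i*} w_{i*} sum_{(i,j) in Q(x,i*)} gamma^{i-i*} w_ij(f)

whose tanh replaces the two caching-weight terms of the caching preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

REPLAY_OUTCOMES = ("pilfered", "fresh_food_item", "degraded_food_item", "not_inspected")
GAP_MINUTES = 60.0
CONTEXT_WINDOW = 3
REPLAY_HORIZON = 6


@dataclass
class ReplayParameters:
    alpha_hunger: float = 0.3
    alpha_fresh: float = 0.5
    alpha_degrade: float = 0.5
    alpha_pilfer: float = 0.5
    theta_fresh: float = 0.99  # hunger threshold in the fresh term
    gamma: float = 0.7  # discount factor in [0, 1]
    similarity_outcome_sign: str = "as_printed"  # or "agreement_rewards"


@dataclass
class _Item:
    triples: list  # of [tray, hunger dict, outcome]
    t: float  # time of last change


@dataclass
class ReplayMemory:
    items: list[_Item] = field(default_factory=list)


def record_interaction(mem: ReplayMemory, tray: int, h: dict[str, float],
                       outcome: str, t: float) -> ReplayMemory:
    """Store an interaction with ``tray`` at time ``t`` (minutes)."""
    if outcome not in REPLAY_OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    h = dict(h)
    if mem.items and t < mem.items[-1].t:
        raise ValueError("interactions must be recorded in time order")
    if mem.items and t - mem.items[-1].t < GAP_MINUTES:
        item = mem.items[-1]
        for triple in item.triples:
            if triple[0] == tray:
                triple[1] = {f: 0.5 * triple[1][f] + 0.5 * h[f] for f in h}
                triple[2] = outcome
                item.t = t
                return mem
        item.triples.append([tray, h, outcome])
        item.t = t
    else:
        mem.items.append(_Item(triples=[[tray, h, outcome]], t=t))
    return mem


def _tray_sequence_match(item_a: _Item, item_b: _Item) -> bool:
    """Exact tray-sequence agreement; differing lengths count as non-match."""
    if len(item_a.triples) != len(item_b.triples):
        return False
    return all(ta[0] == tb[0] for ta, tb in zip(item_a.triples, item_b.triples))


def _similarity(mem: ReplayMemory, i_star: int, I: int,
                params: ReplayParameters) -> float:
    """Context similarity weight w_{i*} over the 3-item window."""
    total = 0.0
    for k in range(CONTEXT_WINDOW):
        ia, ib = I - k, i_star - k
        if ia < 0 or ib < 0:
            continue
        a, b = mem.items[ia], mem.items[ib]
        J = min(len(a.triples), len(b.triples))
        if J == 0:
            continue
        acc = 0.0
        for j in range(J):
            h_a, h_b = a.triples[j][1], b.triples[j][1]
            dist = sum(abs(h_a[f] - h_b[f]) for f in h_a)
            same = a.triples[j][2] == b.triples[j][2]
            if params.similarity_outcome_sign == "as_printed":
                o_term = 1.0 if same else 0.0
            else:  # agreement_rewards: outcome agreement lowers the penalty
                o_term = 0.0 if same else 1.0
            dim_h = len(h_a)
            acc += 1.0 - (dist + o_term) / (dim_h + 1.0)
        total += acc / len(b.triples)
    return total / CONTEXT_WINDOW


def find_replay_indices(mem: ReplayMemory,
                        params: ReplayParameters) -> dict[int, float]:
    """Best-matching past positions with their similarity weights.

    Compares the tray sequences of the last three items against every
    earlier position i < I; returns {} if the best match count is zero.
    Offsets that reach before the start of the history contribute no match.
    """
    I = len(mem.items) - 1
    if I < 0:
        return {}
    best = 0
    scores: dict[int, int] = {}
    for i in range(I):
        count = 0
        for k in range(CONTEXT_WINDOW):
            ia, ib = I - k, i - k
            if ia < 0 or ib < 0:
                continue
            if _tray_sequence_match(mem.items[ia], mem.items[ib]):
                count += 1
        scores[i] = count
        best = max(best, count)
    if best == 0:
        return {}
    return {
        i: _similarity(mem, i, I, params)
        for i, c in scores.items()
        if c == best
    }


def caching_weight(mem: ReplayMemory, food_type: str, tray: int,
                   params: ReplayParameters) -> float:
    """Replay-derived caching weight tanh(w_fx) in (-1, 1)."""
    indices = find_replay_indices(mem, params)
    if not indices:
        return 0.0
    total = 0.0
    for i_star, w_sim in indices.items():
        contrib = 0.0
        for i in range(i_star + 1, min(i_star + REPLAY_HORIZON, len(mem.items) - 1) + 1):
            for triple in mem.items[i].triples:
                if triple[0] != tray:
                    continue
                h_if = triple[1].get(food_type, 0.0)
                o = triple[2]
                w_ij = params.alpha_hunger * h_if
                if o == "fresh_food_item" and h_if <= params.theta_fresh:
                    w_ij += params.alpha_fresh
                elif o == "degraded_food_item":
                    w_ij -= params.alpha_degrade
                elif o == "pilfered":
                    w_ij -= params.alpha_pilfer
                contrib += (params.gamma ** (i - i_star)) * w_ij
        total += w_sim * contrib
    return math.tanh(total)


def dump_jsonl(mem: ReplayMemory) -> str:
    """One JSON line per memory item, for inspection and fixtures."""
    import json

    lines = []
    for item in mem.items:
        lines.append(json.dumps({
            "t": item.t,
            "triples": [[tr, h, o] for tr, h, o in item.triples],
        }, sort_keys=True))
    return "\n".join(lines)
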