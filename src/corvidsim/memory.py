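"""What-where-when memory: hetero-associative network with systems consolidation.

Caching events grow synapses from tray-feature neurons (appearance and
position, a two-hot code) to food-type neurons in the first of seven memory
sub-networks.  A nightly consolidation step moves each trace one layer deeper
on a fixed schedule (one day in each of layers 1-4, three days in layer 5,
eight days in layer 6, layer 7 terminal), so at recall time the *identity of
the active layer* codes the age of the memory:

    layer   1       2       3       4       5       6       7
    age   [0,1)   [1,2)   [2,3)   [3,4)   [4,7)   [7,15)  [15,inf)  days

Each trace is a non-negative consolidation counter per (food, feature); the
effective binary weight is the Heaviside of the counter, with a one-hour
delay after encoding before a fresh trace becomes recallable.  Inspections
decrement counters; re-caching at a site whose trace already sits in a deeper
layer deletes the old trace and restarts at layer 1 (one-hot in time: a
memory lives in exactly one layer).

Per-layer readout weights v^(l)_f encode the expected freshness of food f of
that age; they adapt by a delta rule towards the freshness experienced at
successful retrievals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

N_LAYERS = 7
#: days a trace dwells in each non-terminal layer before moving on
DWELL_DAYS = {1: 1, 2: 1, 3: 1, 4: 1, 5: 3, 6: 8}
ENCODING_DELAY_MIN = 60.0  # one hour before a fresh trace is recallable
MINUTES_PER_DAY = 1440.0


def age_to_layer(age_days: float) -> int:
    """Layer holding a trace of the given age under the daily schedule."""
    if age_days < 0:
        raise ValueError("age must be non-negative")
    boundaries = (1, 2, 3, 4, 7, 15)
    for layer, b in enumerate(boundaries, start=1):
        if age_days < b:
            return layer
    return 7


@dataclass
class _Trace:
    layer: int = 1
    count: float = 0.0
    encoded_at: float = 0.0  # time of the most recent layer-1 encoding
    days_in_layer: int = 0


@dataclass
class MemoryState:
    """Sparse trace store plus readout weights.

    ``traces`` maps (food_type, feature) -> _Trace where a feature is an
    ("a", appearance) or ("p", position) tuple.  ``v`` maps (layer, food)
    -> readout weight in [0, 1]; missing entries default to ``v_init``
    (naive birds expect cached food to still be fresh).
    """

    traces: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    v_init: float = 1.0
    last_tick_day: int = -1

    def readout(self, layer: int, food_type: str) -> float:
        return self.v.get((layer, food_type), self.v_init)


def encode_caching_event(mem: MemoryState, food_type: str, features, t: float) -> MemoryState:
    """Register a caching event of ``food_type`` at a tray's two features."""
    for feat in features:
        key = (food_type, feat)
        tr = mem.traces.get(key)
        if tr is None:
            mem.traces[key] = _Trace(layer=1, count=1.0, encoded_at=t)
        elif tr.layer == 1:
            tr.count += 1.0
            # delay clock restarts only if the trace had been fully erased
            if tr.count == 1.0:
                tr.encoded_at = t
        else:
            # re-caching at an old site replaces the deep trace by a fresh one
            mem.traces[key] = _Trace(layer=1, count=1.0, encoded_at=t)
    return mem


def consolidate(mem: MemoryState, t: float) -> MemoryState:
    """Nightly consolidation tick at time ``t`` (minutes).

    Layer-1 traces encoded less than one hour before the tick are not yet
    effective and stay put; everything else advances per the dwell schedule.
    """
    day = int(t // MINUTES_PER_DAY)
    if day == mem.last_tick_day:
        raise ValueError(f"consolidation already ticked for day {day}")
    mem.last_tick_day = day
    for key, tr in list(mem.traces.items()):
        if tr.count <= 0.0:
            del mem.traces[key]
            continue
        if tr.layer == 1 and t - tr.encoded_at < ENCODING_DELAY_MIN:
            continue
        if tr.layer >= N_LAYERS:
            continue
        tr.days_in_layer += 1
        if tr.days_in_layer >= DWELL_DAYS[tr.layer]:
            tr.layer += 1
            tr.days_in_layer = 0
    return mem


def _effective(tr: _Trace, t: float) -> bool:
    if tr.count <= 0.0:
        return False
    if tr.layer == 1 and t - tr.encoded_at < ENCODING_DELAY_MIN:
        return False
    return True


def recall(mem: MemoryState, features, t: float) -> dict[tuple[int, str], float]:
    """Activations phi^(l)_f triggered by perceiving a tray with ``features``.

    Returns a sparse {(layer, food): activation} map; with binary weights and
    a two-hot tray code the clipped-linear activation is 0 or 1, so only
    active (layer, food) pairs are reported (value 1.0).
    """
    acts: dict[tuple[int, str], float] = {}
    for feat in features:
        for (food, f2), tr in mem.traces.items():
            if f2 == feat and _effective(tr, t):
                key = (tr.layer, food)
                acts[key] = min(1.0, acts.get(key, 0.0) + 1.0)
    return acts


def on_inspection(mem: MemoryState, features, t: float) -> MemoryState:
    """Decrement trace counters at an inspected site (floor at zero).

    The decrement applies to every food type with a trace at the inspected
    features: probing the site examines it regardless of which food the bird
    expected there.
    """
    for key, tr in list(mem.traces.items()):
        if key[1] in features:
            tr.count = max(0.0, tr.count - 1.0)
            if tr.count <= 0.0:
                del mem.traces[key]
    return mem


def update_readout(mem: MemoryState, food_type: str, layer: int,
                   phi_fresh: float, alpha_fresh: float) -> MemoryState:
    """Delta rule on the expected-freshness readout after a successful retrieval."""
    if not 0.0 <= alpha_fresh <= 1.0:
        raise ValueError("alpha_fresh must be in [0, 1]")
    v = mem.readout(layer, food_type)
    mem.v[(layer, food_type)] = v + alpha_fresh * (phi_fresh - v)
    return mem


def active_layers(mem: MemoryState, food_type: str, feature, t: float) -> list[int]:
    """Layers with an effective trace for (food, feature); at most one."""
    tr = mem.traces.get((food_type, feature))
    return [tr.layer] if tr is not None and _effective(tr, t) else []


def snapshot(mem: MemoryState, t: float) -> str:
    """JSON dump of the memory state (for debugging and test fixtures)."""
    layers: dict[int, list] = {l: [] for l in range(1, N_LAYERS + 1)}
    for (food, feat), tr in mem.traces.items():
        layers[tr.layer].append(
            {"food": food, "feature": list(feat), "count": tr.count,
             "effective": _effective(tr, t)}
        )
    return json.dumps(
        {"time_min": t, "layers": {str(k): v for k, v in layers.items() if v},
         "readout": {f"{l}:{f}": w for (l, f), w in mem.v.items()}},
        sort_keys=True,
    )
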