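"""Bird assembly and the per-bird event loop.

A simulated bird is a continuous-time agent.  Between events its
motivational variables (and the hunger-gated growth of caching weights)
evolve by closed-form integration; at self-generated decision instants it
attends to the available objects (loose food, open caching trays), selects
an action by rejection sampling and applies the action's effects to cage and
internal state.  Decision instants are generated by the post-action
time-outs themselves: act, idle u ~ U[1, delta] seconds, act again.  No
events are simulated while the cage holds neither food nor open trays.

Model variants:

``plastic_caching``
    full model: motivation + associative memory + plastic caching weights.
``planning_by_replay``
    caching weights replaced by the episodic replay planner; everything
    else identical.
``no_plasticity``
    caching weights held at zero in the caching preference (memory and
    readout learning stay active).
``no_plasticity_no_memory``
    additionally the memory activations are held at zero.
``no_plasticity_no_memory_no_motivation``
    additionally hunger is held at zero: constant action preferences.

Orthogonally, the caching preference's motivational term can be
hunger-modulated (default), unmodulated, or caching-modulated (driven by a
caching-drive variable depleted by recent caching).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from . import memory as am
from . import motivation as mot
from . import plasticity as cp
from . import policy
from . import replay as rp
from .objects import CageEnvironment, FoodItem
from .parameters import BirdParameters

VARIANTS = (
    "plastic_caching",
    "planning_by_replay",
    "no_plasticity",
    "no_plasticity_no_memory",
    "no_plasticity_no_memory_no_motivation",
)
CACHING_VARIANTS = ("hunger_modulated", "unmodulated", "caching_modulated")

#: nightly consolidation tick: 20 h after the (08:00) start of day 0, i.e. 04:00
TICK_OFFSET_MIN = 1200.0
MINUTES_PER_DAY = 1440.0
SECONDS_PER_MINUTE = 60.0


@dataclass
class Event:
    t: float
    action: str
    food_type: str | None = None
    tray: int | None = None
    outcome: str | None = None


class Bird:
    """Internal state of one simulated bird."""

    def __init__(self, variant: str, params: BirdParameters, seed: int,
                 food_types, caching_variant: str = "hunger_modulated",
                 h0: float = 1.0):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; valid: {VARIANTS}")
        if caching_variant not in CACHING_VARIANTS:
            raise ValueError(
                f"unknown caching variant {caching_variant!r}; valid: {CACHING_VARIANTS}")
        self.variant = variant
        self.caching_variant = caching_variant
        self.params = params
        self.food_types = tuple(food_types)
        self.rng = random.Random(seed)
        self.mparams = mot.MotivationParameters(
            tau_s=params.tau_s, tau_d=params.tau_d, tau_h=params.tau_h,
            n=params.n, c0=params.c0)
        self.motivation = mot.MotivationState.initial(self.food_types, h0=h0)
        self.memory = am.MemoryState()
        self.pparams = cp.PlasticityParameters(
            alpha_fresh=params.alpha_fresh, alpha_pilfer=params.alpha_pilfer,
            alpha_degrade=params.alpha_degrade, alpha_reward=params.alpha_reward,
            tau_hungry=params.tau_hungry, w0_cache=params.w0_cache)
        self.cweights = cp.CachingWeights(w0=params.w0_cache)
        self.rparams = rp.ReplayParameters(
            alpha_hunger=params.alpha_hunger, alpha_fresh=params.alpha_fresh,
            alpha_degrade=params.alpha_degrade, alpha_pilfer=params.alpha_pilfer,
            theta_fresh=params.theta_fresh, gamma=params.gamma)
        self.replay = rp.ReplayMemory()
        self.t_next_decision = -math.inf
        self.next_tick = TICK_OFFSET_MIN
        self.events: list[Event] = []
        self.last_tray_interaction: dict[int, float] = {}

    # -- lesion-aware state accessors -------------------------------------
    @property
    def lesion_motivation(self) -> bool:
        return self.variant == "no_plasticity_no_memory_no_motivation"

    @property
    def lesion_memory(self) -> bool:
        return self.variant in ("no_plasticity_no_memory",
                                "no_plasticity_no_memory_no_motivation")

    @property
    def lesion_caching_weights(self) -> bool:
        return self.variant in ("no_plasticity", "no_plasticity_no_memory",
                                "no_plasticity_no_memory_no_motivation")

    def eff_h(self, f: str) -> float:
        return 0.0 if self.lesion_motivation else self.motivation.h[f]

    def cache_drive(self, f: str) -> float:
        if self.lesion_motivation:
            return 0.0
        if self.caching_variant == "caching_modulated":
            return self.motivation.c[f]
        return self.motivation.h[f]


def make_bird(variant: str, params: BirdParameters, seed: int, food_types,
              caching_variant: str = "hunger_modulated", h0: float = 1.0) -> Bird:
    """Wire up a bird of the requested model variant."""
    return Bird(variant, params, seed, food_types,
                caching_variant=caching_variant, h0=h0)


class Session:
    """One bird in one cage; drives the event loop during ``wait`` periods."""

    def __init__(self, bird: Bird, env: CageEnvironment | None = None):
        self.bird = bird
        self.env = env if env is not None else CageEnvironment()
        self.records: dict[str, float] = {}
        self._tray_added_at: dict[int, float] = {}

    # -- experimenter-side helpers (used by the protocol layer) ------------
    def note_tray_added(self, appearance: int) -> None:
        self._tray_added_at[appearance] = self.env.clock

    def note_tray_removed(self, appearance: int) -> None:
        added = self._tray_added_at.pop(appearance, None)
        if self.bird.variant != "planning_by_replay" or added is None:
            return
        last = self.bird.last_tray_interaction.get(appearance, -math.inf)
        if last < added:
            # perceived but never inspected during this presence
            h = {f: self.bird.eff_h(f) for f in self.bird.food_types}
            rp.record_interaction(self.bird.replay, appearance, h,
                                  "not_inspected", self.env.clock)

    # -- continuous dynamics ----------------------------------------------
    def _advance(self, dt: float) -> None:
        if dt <= 0.0:
            return
        bird = self.bird
        if (bird.variant == "plastic_caching" and not bird.lesion_motivation):
            feats = [f for tr in self.env.open_trays() for f in tr.features]
            if feats:
                gated = mot.gated_time_above(
                    bird.motivation, dt, cp.THETA_HUNGRY, bird.mparams,
                    self.env.maintenance_diet)
                cp.grow_while_hungry(bird.cweights, bird.food_types, feats,
                                     gated, bird.pparams)
        mot.propagate(bird.motivation, dt, bird.mparams,
                      self.env.maintenance_diet)

    def advance_to(self, t_end: float, simulate_events: bool = True) -> None:
        """Advance clock to ``t_end``, firing bird decisions and nightly ticks."""
        env, bird = self.env, self.bird
        while True:
            acting = simulate_events and env.has_relevant_objects()
            if acting and bird.t_next_decision < env.clock:
                u = policy.draw_timeout_seconds("other", bird.params, bird.rng)
                bird.t_next_decision = env.clock + u / SECONDS_PER_MINUTE
            t_next = t_end
            if acting and bird.t_next_decision < t_next:
                t_next = bird.t_next_decision
            fire_tick = bird.next_tick <= t_next
            if fire_tick:
                t_next = bird.next_tick
            self._advance(t_next - env.clock)
            env.clock = t_next
            if fire_tick:
                am.consolidate(bird.memory, t_next)
                bird.next_tick += MINUTES_PER_DAY
                continue
            if t_next >= t_end:
                return
            self._act()

    def wait(self, minutes: float) -> None:
        if minutes <= 0.0:
            raise ValueError("wait duration must be positive")
        self.advance_to(self.env.clock + minutes)

    # -- decision instant --------------------------------------------------
    def _candidates(self) -> list[policy.ActionCandidate]:
        env, bird, p = self.env, self.bird, self.bird.params
        t = env.clock
        cands = [policy.ActionCandidate("other", None, None, p.p_other)]
        for f in env.eatable_food_types():
            if f not in p.v_eat:
                continue
            pref = policy.eat_preference(p.v_eat[f], bird.eff_h(f), p.eta_eat)
            cands.append(policy.ActionCandidate("eat", f, None, pref))
        open_trays = env.open_trays()
        if open_trays:
            replay_indices = None
            for f in env.cacheable_food_types():
                if f not in p.v_cache:
                    continue
                drive = bird.cache_drive(f)
                for tr in open_trays:
                    if bird.variant == "planning_by_replay":
                        wrep = rp.caching_weight(bird.replay, f, tr.appearance,
                                                 bird.rparams)
                        pref = policy.cache_preference(
                            0.0, 0.0, p.v_cache[f], drive, p.eta_cache,
                            variant=bird.caching_variant, replay_weight=wrep)
                    else:
                        if bird.lesion_caching_weights:
                            wp = wa = 0.0
                        else:
                            fa, fp = tr.features
                            wa = bird.cweights.get(f, fa)
                            wp = bird.cweights.get(f, fp)
                        pref = policy.cache_preference(
                            wp, wa, p.v_cache[f], drive, p.eta_cache,
                            variant=bird.caching_variant)
                    cands.append(policy.ActionCandidate("cache", f, tr.appearance, pref))
            h_eff = {f: bird.eff_h(f) for f in bird.food_types if f in p.v_eat}
            v_insp = {f: p.v_inspect(f) for f in h_eff}
            for tr in open_trays:
                acts = ({} if bird.lesion_memory
                        else am.recall(bird.memory, tr.features, t))
                pref = policy.inspect_preference(
                    acts, bird.memory.readout, v_insp, h_eff, p.eta_inspect)
                cands.append(policy.ActionCandidate("retrieve", None, tr.appearance, pref))
        return cands

    def _act(self) -> None:
        env, bird = self.env, self.bird
        t = env.clock
        cand, _ = policy.select_action(self._candidates(), bird.rng)
        outcome = None
        if cand.kind == "eat":
            env.loose[cand.food_type] -= 1
            env.eaten[cand.food_type] = env.eaten.get(cand.food_type, 0) + 1
            mot.on_eat(bird.motivation, cand.food_type, bird.mparams)
        elif cand.kind == "cache":
            env.loose[cand.food_type] -= 1
            tray = env.tray(cand.tray)
            tray.cached.append((FoodItem(cand.food_type), t))
            if not bird.lesion_memory:
                am.encode_caching_event(bird.memory, cand.food_type,
                                        tray.features, t)
            if bird.caching_variant == "caching_modulated":
                mot.on_cache(bird.motivation, cand.food_type, bird.mparams)
            if bird.variant == "planning_by_replay":
                self._replay_note(cand.tray, None, t)
            bird.last_tray_interaction[cand.tray] = t
        elif cand.kind == "retrieve":
            outcome = self._retrieve(cand.tray)
        bird.events.append(Event(t, cand.kind, cand.food_type, cand.tray, outcome))
        u = policy.draw_timeout_seconds(cand.kind, bird.params, bird.rng)
        bird.t_next_decision = t + u / SECONDS_PER_MINUTE

    def _retrieve(self, appearance: int) -> str:
        env, bird, p = self.env, self.bird, self.bird.params
        t = env.clock
        tray = env.tray(appearance)
        env.notify_retrieve(t, appearance)
        bird.last_tray_interaction[appearance] = t
        recall_acts = ({} if bird.lesion_memory
                       else am.recall(bird.memory, tray.features, t))
        if tray.cached:
            idx = int(bird.rng.random() * len(tray.cached))
            item, _ts = tray.cached.pop(idx)
            if item.freshness > 0.0:
                outcome = "fresh_food_item"
                # a retrieved fresh item re-enters the perceived food pool
                env.loose[item.food_type] = env.loose.get(item.food_type, 0) + 1
            else:
                outcome = "degraded_food_item"
                env.discarded[item.food_type] = env.discarded.get(item.food_type, 0) + 1
            retrieved_type = item.food_type
        else:
            outcome = "pilfered"
            retrieved_type = None
        # readout learning at successful retrievals (active in all variants
        # that keep the associative memory)
        if not bird.lesion_memory:
            if outcome != "pilfered":
                phi_fresh = 1.0 if outcome == "fresh_food_item" else 0.0
                for (layer, food) in recall_acts:
                    if food == retrieved_type:
                        am.update_readout(bird.memory, food, layer, phi_fresh,
                                          p.alpha_fresh)
            am.on_inspection(bird.memory, set(tray.features), t)
        # three-factor caching-weight update for recalled food types
        if bird.variant == "plastic_caching" and recall_acts:
            if outcome == "pilfered":
                touched = {food for (_l, food) in recall_acts}
            else:
                touched = {retrieved_type} if any(
                    food == retrieved_type for (_l, food) in recall_acts) else set()
            for f in touched:
                p_eat_f = policy.eat_preference(
                    p.v_eat.get(f, 0.0), bird.eff_h(f), p.eta_eat)
                cp.apply_retrieval_outcome(bird.cweights, f, tray.features,
                                           outcome, p_eat_f, bird.pparams)
        if bird.variant == "planning_by_replay":
            self._replay_note(appearance, outcome, t)
        return outcome

    def _replay_note(self, appearance: int, outcome: str | None, t: float) -> None:
        """Record a tray interaction in the replay buffer.

        ``outcome=None`` marks a caching interaction: it must not overwrite a
        retrieval outcome already stored for the same tray in the current
        item, so it only refreshes the stored hunger vector in that case.
        """
        bird = self.bird
        h = {f: bird.eff_h(f) for f in bird.food_types}
        mem = bird.replay
        if outcome is None:
            if mem.items and t - mem.items[-1].t < rp.GAP_MINUTES:
                for triple in mem.items[-1].triples:
                    if triple[0] == appearance:
                        triple[1] = {f: 0.5 * triple[1][f] + 0.5 * h[f] for f in h}
                        mem.items[-1].t = t
                        return
            outcome = "not_inspected"
        rp.record_interaction(mem, appearance, h, outcome, t)


def event_log_rows(bird: Bird, bird_id=0) -> list[tuple]:
    """Event-log rows (bird_id, time_min, action, food_type, tray, outcome)."""
    return [(bird_id, e.t, e.action, e.food_type, e.tray, e.outcome)
            for e in bird.events]


def run_population(protocol, population, K: int, seed: int,
                   n_per_group=None) -> list:
    """Simulate ``K`` independent groups of freshly sampled birds.

    ``population`` must provide ``sample_parameters(rng) -> BirdParameters``
    and the attributes ``variant`` and ``caching_variant``.  Returns one
    summary dataset per repetition.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = random.Random(seed)
    datasets = []
    for _ in range(K):
        datasets.append(run_once(protocol, population, rng.randrange(2 ** 31),
                                 n_per_group=n_per_group))
    return datasets


def run_once(protocol, population, seed: int, n_per_group=None):
    """One protocol run with a freshly sampled group of birds."""
    rng = random.Random(seed)
    birds_by_group: dict[str, list[Bird]] = {}
    for group, n_default in protocol.group_sizes.items():
        n = n_default
        if isinstance(n_per_group, dict):
            n = n_per_group.get(group, n_default)
        elif n_per_group is not None:
            n = int(n_per_group)
        birds_by_group[group] = [
            make_bird(population.variant,
                      population.sample_parameters(rng),
                      rng.randrange(2 ** 31),
                      protocol.food_types,
                      caching_variant=population.caching_variant)
            for _ in range(n)
        ]
    return protocol.run(birds_by_group, rng)
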