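"""Event loop: retrieval outcomes, lesions, determinism, dense-oracle snapshots."""

import math

import pytest

from corvidsim.fixtures import load_protocol, point_population, tuned_parameters
from corvidsim.objects import CageEnvironment, FoodItem, Tray
from corvidsim.parameters import BirdParameters, default_parameters
from corvidsim.policy import sigma
from corvidsim.simulator import Session, make_bird, run_once, run_population


def _cached_tray(food="mealworm", fresh=True, n=1):
    tray = Tray(appearance=1, position=1)
    for _ in range(n):
        item = FoodItem(food)
        if not fresh:
            item.freshness = 0.0
        tray.cached.append((item, 0.0))
    return tray


def _bird_with_memory(variant="plastic_caching", food="mealworm"):
    params = tuned_parameters("dekort07_exp4")
    params.n.setdefault(food, 0.3)
    params.v_eat.setdefault(food, 0.3)
    params.v_cache.setdefault(food, 0.3)
    bird = make_bird(variant, params, 0, [food])
    return bird


def test_unknown_variant_lists_valid_tags():
    with pytest.raises(ValueError, match="plastic_caching"):
        make_bird("bogus", BirdParameters(), 0, ["mealworm"])


def test_retrieve_pilfered_decreases_caching_weight():
    bird = _bird_with_memory()
    tray = Tray(appearance=1, position=1)
    env = CageEnvironment()
    env.add_tray(tray)
    s = Session(bird, env)
    from corvidsim.memory import encode_caching_event

    encode_caching_event(bird.memory, "mealworm", tray.features, -120.0)
    w0 = bird.cweights.get("mealworm", tray.features[0])
    outcome = s._retrieve(1)
    assert outcome == "pilfered"
    w1 = bird.cweights.get("mealworm", tray.features[0])
    assert w1 == pytest.approx(w0 * (1 - bird.params.alpha_pilfer))
    # readout untouched by an unsuccessful retrieval
    assert bird.memory.readout(1, "mealworm") == 1.0


def test_retrieve_degraded_lowers_readout_and_weight():
    bird = _bird_with_memory(food="cricket")
    tray = _cached_tray("cricket", fresh=False)
    env = CageEnvironment()
    env.add_tray(tray)
    s = Session(bird, env)
    from corvidsim.memory import encode_caching_event

    encode_caching_event(bird.memory, "cricket", tray.features, -120.0)
    w0 = bird.cweights.get("cricket", tray.features[0])
    outcome = s._retrieve(1)
    assert outcome == "degraded_food_item"
    assert bird.memory.readout(1, "cricket") == pytest.approx(
        1.0 - bird.params.alpha_fresh)
    assert bird.cweights.get("cricket", tray.features[0]) == pytest.approx(
        w0 * (1 - bird.params.alpha_degrade))
    # the degraded item was discarded, not returned to the cage
    assert env.count_food_items() == 0
    assert env.discarded["cricket"] == 1


def test_retrieve_fresh_reenters_food_pool_and_grows_weight():
    bird = _bird_with_memory()
    tray = _cached_tray("mealworm", fresh=True)
    env = CageEnvironment()
    env.add_tray(tray)
    s = Session(bird, env)
    from corvidsim.memory import encode_caching_event

    encode_caching_event(bird.memory, "mealworm", tray.features, -120.0)
    w0 = bird.cweights.get("mealworm", tray.features[0])
    outcome = s._retrieve(1)
    assert outcome == "fresh_food_item"
    assert env.loose["mealworm"] == 1
    p_eat = sigma(bird.params.v_eat["mealworm"] * bird.motivation.h["mealworm"]
                  + bird.params.eta_eat)
    assert bird.cweights.get("mealworm", tray.features[0]) == pytest.approx(
        w0 + bird.params.alpha_fresh * p_eat * (1 - w0))


def test_retrieve_without_recall_updates_nothing():
    bird = _bird_with_memory()
    tray = _cached_tray("mealworm", fresh=True)
    env = CageEnvironment()
    env.add_tray(tray)
    s = Session(bird, env)
    w0 = bird.cweights.get("mealworm", tray.features[0])
    s._retrieve(1)  # the bird never cached here: no eligibility
    assert bird.cweights.get("mealworm", tray.features[0]) == w0


def test_triple_lesion_constant_preferences():
    params = default_parameters(["mealworm"])
    params.eta_eat = 0.3
    params.eta_cache = 0.4
    params.eta_inspect = 0.2
    bird = make_bird("no_plasticity_no_memory_no_motivation", params, 0,
                     ["mealworm"])
    env = CageEnvironment()
    env.add_food(FoodItem("mealworm", amount=2))
    env.add_tray(Tray(appearance=1, position=1))
    s = Session(bird, env)
    prefs = {(c.kind, c.food_type, c.tray): c.preference for c in s._candidates()}
    assert prefs[("eat", "mealworm", None)] == pytest.approx(0.3)
    assert prefs[("cache", "mealworm", 1)] == pytest.approx(0.4)
    assert prefs[("retrieve", None, 1)] == pytest.approx(0.2)


def test_no_plasticity_bird_still_learns_readout():
    bird = _bird_with_memory("no_plasticity", food="cricket")
    tray = _cached_tray("cricket", fresh=False)
    env = CageEnvironment()
    env.add_tray(tray)
    s = Session(bird, env)
    from corvidsim.memory import encode_caching_event

    encode_caching_event(bird.memory, "cricket", tray.features, -120.0)
    s._retrieve(1)
    assert bird.memory.readout(1, "cricket") < 1.0  # readout plasticity active
    # but caching weights are lesioned out of the preference
    prefs = [c for c in s._candidates() if c.kind == "cache"]
    assert prefs == []  # no loose food; nothing to cache


def test_unmodulated_caching_insensitive_to_hunger():
    params = tuned_parameters("dekort07_exp4")
    for h0 in (0.0, 1.0):
        bird = make_bird("plastic_caching", params, 0, ["mealworm"],
                         caching_variant="unmodulated", h0=h0)
        env = CageEnvironment()
        env.add_food(FoodItem("mealworm", amount=1))
        env.add_tray(Tray(appearance=1, position=1))
        pref = [c for c in Session(bird, env)._candidates()
                if c.kind == "cache"][0].preference
        if h0 == 0.0:
            base = pref
    assert pref == pytest.approx(base)


def test_determinism_per_variant():
    protocol = load_protocol("dekort07_exp4")
    for variant in ("plastic_caching", "planning_by_replay", "no_plasticity",
                    "no_plasticity_no_memory",
                    "no_plasticity_no_memory_no_motivation"):
        pop = point_population("dekort07_exp4", variant=variant)
        d1 = run_once(protocol, pop, 11)
        d2 = run_once(protocol, pop, 11)
        assert d1.values == d2.values


def test_run_population_first_dataset_stable_under_k():
    protocol = load_protocol("specific_satiety")
    pop = point_population("specific_satiety")
    ds2 = run_population(protocol, pop, 2, seed=5)
    ds1 = run_population(protocol, pop, 1, seed=5)
    assert ds1[0].values == ds2[0].values
    with pytest.raises(ValueError):
        run_population(protocol, pop, 0, seed=5)


def test_event_log_totally_ordered():
    protocol = load_protocol("dekort07_exp4")
    bird = make_bird("plastic_caching", tuned_parameters("dekort07_exp4"),
                     9, protocol.food_types)
    session = Session(bird)
    from corvidsim.protocol import apply_step

    for step in protocol.spec["steps"]:
        if "groups" in step and "control" not in step["groups"]:
            continue
        apply_step(session, step, protocol.spec["trays"])
    times = [e.t for e in bird.events]
    assert times == sorted(times)
    assert len(times) > 20  # the bird was actually busy
    outcomes = {e.outcome for e in bird.events if e.action == "retrieve"}
    assert outcomes <= {"pilfered", "fresh_food_item", "degraded_food_item"}
    assert all(e.outcome is None for e in bird.events if e.action != "retrieve")
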