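"""Manipulable objects of the experimental cage: food, caching trays, observers.

Experiments on food-caching birds are formalized as programs acting on three
object types -- food items, visually distinct caching trays, and inspection
observers that passively log which trays a bird probes.  The cage environment
holds these objects together with a simulated clock (in minutes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

FOOD_TYPES = (
    "mealworm",
    "waxworm",
    "peanut",
    "suet_pellet",
    "pinenut",
    "kibble",
    "cricket",
    "pineapple",
    "salami",
    "stone",
    "maintenance_diet",
)

#: stones can be cached but never eaten
NON_EATABLE = frozenset({"stone"})


@dataclass
class FoodItem:
    """A batch of identical food items.

    ``freshness`` is a unitless palatability in [0, 1]; degraded items have
    freshness 0 but remain encounterable.  ``amount`` counts identical items.
    """

    food_type: str
    freshness: float = 1.0
    amount: int = 1
    eatable: bool | None = None
    cacheable: bool = True

    def __post_init__(self) -> None:
        if self.food_type not in FOOD_TYPES:
            raise ValueError(f"unknown food type {self.food_type!r}")
        if not 0.0 <= self.freshness <= 1.0:
            raise ValueError("freshness must be in [0, 1]")
        if self.amount < 0:
            raise ValueError("amount must be non-negative")
        if self.eatable is None:
            self.eatable = self.food_type not in NON_EATABLE
        if self.food_type in NON_EATABLE and self.eatable:
            raise ValueError(f"{self.food_type} is never eatable")


@dataclass
class Tray:
    """A caching tray, identified by its visual appearance.

    ``position`` is an integer location identifier; several trays (e.g. the
    two halves of a physically single tray) may share a position.  Covered
    trays (``open=False``) accept neither caching nor inspection.
    ``cached`` holds (FoodItem, caching-time) pairs, one item per entry.
    """

    appearance: int
    position: int
    open: bool = True
    cached: list[tuple[FoodItem, float]] = field(default_factory=list)

    @property
    def features(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """The two-hot feature code of this tray: appearance and position."""
        return (("a", self.appearance), ("p", self.position))


@dataclass
class InspectionObserver:
    """Passively counts inspections (retrieve actions) of registered trays."""

    name: str
    tray_appearances: list[int]
    log: list[tuple[float, int]] = field(default_factory=list)

    def notify(self, t: float, appearance: int) -> None:
        if appearance in self.tray_appearances:
            if self.log and t < self.log[-1][0]:
                raise ValueError("observer log must be monotone in time")
            self.log.append((t, appearance))

    def inspections(self) -> dict[int, int]:
        counts = {a: 0 for a in self.tray_appearances}
        for _, a in self.log:
            counts[a] += 1
        return counts

    def first_inspection(self):
        """Tray of the earliest logged retrieve, or None if nothing logged."""
        return self.log[0][1] if self.log else None


class CageEnvironment:
    """One bird's cage: clock, loose food, trays, observers.

    All times are in minutes.  Loose food is tracked per food type (the
    experiments never mix degraded and fresh loose food; retrieved degraded
    items are discarded on the spot, so loose food is always fresh).
    """

    def __init__(self) -> None:
        self.clock: float = 0.0
        self.loose: dict[str, int] = {}
        self.trays: dict[int, Tray] = {}
        self.observers: dict[str, InspectionObserver] = {}
        self.maintenance_diet: bool = False
        # conservation bookkeeping
        self.eaten: dict[str, int] = {}
        self.discarded: dict[str, int] = {}
        self.removed: dict[str, int] = {}

    # -- object management -------------------------------------------------
    def add_food(self, item: FoodItem) -> None:
        self.loose[item.food_type] = self.loose.get(item.food_type, 0) + item.amount

    def remove_food(self, food_type: str | None = None) -> int:
        """Remove loose food (all types if ``food_type`` is None); returns count."""
        types = [food_type] if food_type is not None else list(self.loose)
        n = 0
        for ft in types:
            k = self.loose.pop(ft, 0)
            self.removed[ft] = self.removed.get(ft, 0) + k
            n += k
        return n

    def add_tray(self, tray: Tray) -> None:
        if tray.appearance in self.trays:
            raise ValueError(f"tray appearance {tray.appearance} already present")
        self.trays[tray.appearance] = tray

    def remove_tray(self, appearance: int) -> Tray:
        try:
            return self.trays.pop(appearance)
        except KeyError:
            raise KeyError(f"no tray with appearance {appearance}") from None

    def tray(self, appearance: int) -> Tray:
        try:
            return self.trays[appearance]
        except KeyError:
            raise KeyError(f"no tray with appearance {appearance}") from None

    def add_observer(self, obs: InspectionObserver) -> None:
        self.observers[obs.name] = obs

    def remove_observer(self, name: str) -> InspectionObserver:
        return self.observers.pop(name)

    def notify_retrieve(self, t: float, appearance: int) -> None:
        for obs in self.observers.values():
            obs.notify(t, appearance)

    # -- queries -----------------------------------------------------------
    def open_trays(self) -> list[Tray]:
        return [tr for tr in self.trays.values() if tr.open]

    def eatable_food_types(self) -> list[str]:
        return [ft for ft, n in self.loose.items() if n > 0 and ft not in NON_EATABLE]

    def cacheable_food_types(self) -> list[str]:
        return [ft for ft, n in self.loose.items() if n > 0]

    def count_food_items(self) -> int:
        return sum(self.loose.values())

    def has_relevant_objects(self) -> bool:
        """Birds only act when food or open caching trays are available."""
        return any(n > 0 for n in self.loose.values()) or bool(self.open_trays())

    def total_item_count(self) -> int:
        """Loose + cached + eaten + discarded + removed (conservation check)."""
        cached = sum(len(tr.cached) for tr in self.trays.values())
        return (
            sum(self.loose.values())
            + cached
            + sum(self.eaten.values())
            + sum(self.discarded.values())
            + sum(self.removed.values())
        )
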