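"""Per-bird constant parameters, their admissible ranges, and flattening.

Every bird is characterized by a constant parameter vector theta; each
component is constrained to a manually set interval.  Food-specific
parameters (nutritional value, eating and caching preferences) have one
component per food type present in an experiment; for stones only the
caching preference applies.  Population fitting (see ``inference``) places
a rescaled beta density on each interval.

Times: tau_* in minutes, delta_* (post-action time-outs) in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

#: (low, high) ranges per scalar parameter
RANGES: dict[str, tuple[float, float]] = {
    "tau_s": (0.5, 10.0),
    "tau_d": (0.0, 20.0),
    "tau_h": (50.0, 300.0),
    "n": (0.1, 1.0),
    "v_eat": (0.1, 1.0),
    "v_cache": (0.0, 1.0),
    "eta_eat": (-1.0, 1.0),
    "eta_inspect": (-2.0, 0.5),
    "s_inspect": (0.0, 5.0),
    "eta_cache": (-1.0, 1.0),
    "alpha_fresh": (0.0, 1.0),
    "alpha_reward": (0.0, 0.9),
    "alpha_pilfer": (0.0, 0.2),
    "alpha_degrade": (0.0, 0.2),
    "tau_hungry": (100.0, 500.0),
    "w0_cache": (0.0, 1.0),
    "delta_eat": (10.0, 200.0),
    "delta_inspect": (10.0, 200.0),
    "delta_cache": (10.0, 200.0),
    "delta_other": (10.0, 200.0),
    "p_other": (0.0, 1.0),
    # caching-modulated variant
    "c0": (0.0, 1.0),
    # planning-by-replay (ranges not tabulated; kept on [0, 1] scales)
    "alpha_hunger": (0.0, 1.0),
    "gamma": (0.0, 1.0),
}

FOOD_SPECIFIC = ("n", "v_eat", "v_cache")


@dataclass
class BirdParameters:
    """Union of motivation, policy, plasticity and replay parameters."""

    tau_s: float = 5.0
    tau_d: float = 10.0
    tau_h: float = 150.0
    n: dict[str, float] = field(default_factory=dict)
    v_eat: dict[str, float] = field(default_factory=dict)
    v_cache: dict[str, float] = field(default_factory=dict)
    eta_eat: float = 0.0
    eta_inspect: float = -0.5
    s_inspect: float = 1.0
    eta_cache: float = 0.0
    alpha_fresh: float = 0.5
    alpha_reward: float = 0.0
    alpha_pilfer: float = 0.1
    alpha_degrade: float = 0.1
    tau_hungry: float = 300.0
    w0_cache: float = 0.2
    delta_eat: float = 60.0
    delta_inspect: float = 60.0
    delta_cache: float = 60.0
    delta_other: float = 60.0
    p_other: float = 0.3
    c0: float = 0.5
    alpha_hunger: float = 0.3
    gamma: float = 0.7
    theta_fresh: float = 0.99

    def copy(self) -> "BirdParameters":
        return replace(self, n=dict(self.n), v_eat=dict(self.v_eat),
                       v_cache=dict(self.v_cache))

    def validate(self) -> None:
        for name, (lo, hi) in RANGES.items():
            val = getattr(self, name)
            if name in FOOD_SPECIFIC:
                for f, v in val.items():
                    if f == "stone" and name != "v_cache":
                        continue
                    if not lo <= v <= hi:
                        raise ValueError(f"{name}[{f}]={v} outside [{lo}, {hi}]")
            elif not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside [{lo}, {hi}]")

    def v_inspect(self, f: str) -> float:
        """Derived inspection preference: s_inspect * v_eat_f."""
        return self.s_inspect * self.v_eat[f]


@dataclass(frozen=True)
class ParamEntry:
    """One fitted scalar: a parameter name, an optional food type, and bounds."""

    name: str
    food: str | None = None

    @property
    def bounds(self) -> tuple[float, float]:
        return RANGES[self.name]

    @property
    def label(self) -> str:
        return self.name if self.food is None else f"{self.name}[{self.food}]"

    def get(self, params: BirdParameters) -> float:
        val = getattr(params, self.name)
        return val[self.food] if self.food is not None else val

    def set(self, params: BirdParameters, value: float) -> None:
        if self.food is not None:
            getattr(params, self.name)[self.food] = value
        else:
            setattr(params, self.name, value)


def default_parameters(food_types) -> BirdParameters:
    """Mid-range per-food defaults for the given food repertoire."""
    p = BirdParameters()
    for f in food_types:
        if f != "stone":
            p.n[f] = 0.5
            p.v_eat[f] = 0.5
        p.v_cache[f] = 0.5
    return p
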