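"""Reward-modulated plasticity of the caching weights (plastic caching model).

The caching weights w_cache_{f,x} (per food type and tray feature, in [0,1])
change through two terms:

1. An outcome-driven, neoHebbian three-factor update at retrieval attempts.
   Inspecting a cache site reactivates the memory of the food cached there
   (eligibility); the retrieval outcome is the modulatory third factor:

       dw = -alpha_pilfer  * w                 if the cache was pilfered
       dw = -alpha_degrade * w                 if the item was degraded
       dw = +alpha_fresh * p_eat_f * (1 - w)   if the item was fresh

   applied identically to both feature weights (appearance and position) of
   the inspected tray for the recalled food type.

2. A hunger-gated presynaptic growth term: while hunger h_f exceeds the
   threshold theta_hungry = 0.99 and a tray feature x is perceived, the
   weight relaxes towards 1 with time constant tau_hungry,

       w(t) = 1 - (1 - w0) * exp(-t_active / tau_hungry),

   where t_active is the accumulated gated time.  This implements
   compensatory caching: persistent hunger at a place raises the
   propensity to cache there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

THETA_HUNGRY = 0.99  # fixed hunger gate threshold

OUTCOMES = ("pilfered", "degraded_food_item", "fresh_food_item")


@dataclass
class PlasticityParameters:
    alpha_fresh: float = 0.5  # [0, 1]
    alpha_pilfer: float = 0.1  # [0, 0.2]
    alpha_degrade: float = 0.1  # [0, 0.2]
    alpha_reward: float = 0.0  # reserved parameter, unused by default
    tau_hungry: float = 300.0  # [100, 500] min
    w0_cache: float = 0.2  # initial caching weights [0, 1]


@dataclass
class CachingWeights:
    """Sparse {(food_type, feature): weight}; absent entries equal w0."""

    w0: float = 0.2
    w: dict = field(default_factory=dict)

    def get(self, food_type: str, feature) -> float:
        return self.w.get((food_type, feature), self.w0)

    def set(self, food_type: str, feature, value: float) -> None:
        self.w[(food_type, feature)] = value


def weight_rows(weights: CachingWeights, t: float) -> list[tuple]:
    """Sparse snapshot rows (food_type, feature_kind, feature_id, weight, time)."""
    return [(food, kind, ident, w, t)
            for (food, (kind, ident)), w in sorted(weights.w.items())]


def apply_retrieval_outcome(weights: CachingWeights, food_type: str, features,
                            outcome: str, p_eat_f: float,
                            params: PlasticityParameters) -> CachingWeights:
    """Three-factor update after attempting to retrieve ``food_type`` at a tray."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    for feat in features:
        w = weights.get(food_type, feat)
        if outcome == "pilfered":
            w = w - params.alpha_pilfer * w
        elif outcome == "degraded_food_item":
            w = w - params.alpha_degrade * w
        else:
            w = w + params.alpha_fresh * p_eat_f * (1.0 - w)
        weights.set(food_type, feat, w)
    return weights


def grow_while_hungry(weights: CachingWeights, food_types, features,
                      gated_time: dict[str, float],
                      params: PlasticityParameters) -> CachingWeights:
    """Saturating growth of weights for perceived features while very hungry.

    ``gated_time`` gives, per food type, the time (minutes) spent with
    h_f > theta_hungry during the elapsed interval; ``features`` are the
    features of trays that were present and open throughout.
    """
    for f in food_types:
        t_active = gated_time.get(f, 0.0)
        if t_active <= 0.0:
            continue
        decay = math.exp(-t_active / params.tau_hungry)
        for feat in features:
            w = weights.get(f, feat)
            weights.set(f, feat, 1.0 - (1.0 - w) * decay)
    return weights
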