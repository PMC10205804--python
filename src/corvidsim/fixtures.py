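"""Protocol fixtures, hand-tuned bird parameters, and synthetic reference data.

Three protocols reconstructed from the behavioral literature on caching
corvids ship with the package:

``dekort07_exp4``
    cache pilfering: after two training trials in which one group's caches
    in tray A are secretly moved to tray B, pilfered birds cache less in A.
``clayton03_exp2``
    food-specific degradation and generalization: birds taught that
    crickets degrade within three days search the cricket half of a new
    tray less than the peanut half.
``specific_satiety``
    pre-feeding one food selectively suppresses eating of that food; a
    later re-test probes the recovery of appetite.

The synthetic reference generator simulates a known ground-truth population
and emits its summary table in the observed-data CSV schema, so fitting,
reproducibility scoring and recovery studies run fully offline.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources

from .inference import Population
from .parameters import BirdParameters, ParamEntry
from .protocol import Protocol, SummaryDataset
from .simulator import run_population

FIXTURE_NAMES = ("dekort07_exp4", "clayton03_exp2", "specific_satiety")


def load_protocol(name: str) -> Protocol:
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown protocol {name!r}; available: {FIXTURE_NAMES}")
    text = (resources.files("corvidsim") / "fixtures" / f"{name}.yaml").read_text()
    return Protocol.from_yaml(text)


def tuned_parameters(name: str) -> BirdParameters:
    """Hand-tuned (not fitted) bird parameters per fixture.

    Chosen so that action rates are plausible (a decision every half minute
    or so, caching dominant when hungry with food and open trays available)
    and the published qualitative effect is expressed.
    """
    if name == "dekort07_exp4":
        return BirdParameters(
            tau_s=5.0, tau_d=10.0, tau_h=150.0,
            n={"mealworm": 0.3}, v_eat={"mealworm": 0.3},
            v_cache={"mealworm": 0.3},
            eta_eat=-0.2, eta_cache=-0.25, eta_inspect=-0.5, s_inspect=1.0,
            alpha_fresh=0.7, alpha_pilfer=0.2, alpha_degrade=0.2,
            tau_hungry=400.0, w0_cache=0.2,
            delta_eat=45.0, delta_inspect=45.0, delta_cache=45.0,
            delta_other=45.0, p_other=0.2,
        )
    if name == "clayton03_exp2":
        return BirdParameters(
            tau_s=5.0, tau_d=10.0, tau_h=150.0,
            n={"peanut": 0.4, "cricket": 0.4},
            v_eat={"peanut": 0.4, "cricket": 0.4},
            v_cache={"peanut": 0.35, "cricket": 0.35},
            eta_eat=-0.2, eta_cache=-0.2, eta_inspect=-0.5, s_inspect=0.5,
            alpha_fresh=0.6, alpha_pilfer=0.15, alpha_degrade=0.15,
            tau_hungry=400.0, w0_cache=0.2,
            delta_eat=45.0, delta_inspect=45.0, delta_cache=45.0,
            delta_other=45.0, p_other=0.2,
        )
    if name == "specific_satiety":
        return BirdParameters(
            tau_s=4.0, tau_d=8.0, tau_h=120.0,
            n={"mealworm": 0.4, "peanut": 0.4},
            v_eat={"mealworm": 0.7, "peanut": 0.55},
            v_cache={"mealworm": 0.3, "peanut": 0.3},
            eta_eat=0.25, eta_cache=-0.5, eta_inspect=-1.0, s_inspect=1.0,
            alpha_fresh=0.5, alpha_pilfer=0.1, alpha_degrade=0.1,
            tau_hungry=400.0, w0_cache=0.1,
            delta_eat=90.0, delta_inspect=90.0, delta_cache=90.0,
            delta_other=90.0, p_other=0.4,
        )
    raise KeyError(name)


def point_population(name: str, variant: str = "plastic_caching",
                     caching_variant: str = "hunger_modulated") -> Population:
    """Population with zero spread: every bird gets the tuned parameters."""
    return Population(tuned_parameters(name), [], variant=variant,
                      caching_variant=caching_variant)


# ---------------------------------------------------------------------------
# ground-truth scenarios for recovery studies
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthScenario:
    """A known population, a protocol, and a simulation budget."""

    protocol_name: str
    population: Population
    n_per_group: int | None = None
    n_datasets: int = 1000
    seed: int = 0


#: fitted entries of the satiety recovery study (appetite time constant,
#: the two eating preferences, the eating bias)
SATIETY_SPACE = [
    ParamEntry("tau_h"),
    ParamEntry("v_eat", "mealworm"),
    ParamEntry("v_eat", "peanut"),
    ParamEntry("eta_eat"),
]

#: ground-truth hyperparameters (d, s) per entry; deliberately off-center so
#: that recovery has to move away from the flat starting point
SATIETY_TRUE_HYPER = {
    "tau_h": (1.9, 2.5),
    "v_eat[mealworm]": (-1.5, 2.0),
    "v_eat[peanut]": (0.0, 1.0),
    "eta_eat": (-1.0, 1.5),
}


def satiety_ground_truth() -> Population:
    d = [SATIETY_TRUE_HYPER[e.label][0] for e in SATIETY_SPACE]
    s = [SATIETY_TRUE_HYPER[e.label][1] for e in SATIETY_SPACE]
    return Population(tuned_parameters("specific_satiety"),
                      list(SATIETY_SPACE), s=s, d=d)


def satiety_scenario(seed: int = 0, n_datasets: int = 1000) -> GroundTruthScenario:
    return GroundTruthScenario("specific_satiety", satiety_ground_truth(),
                               n_per_group=8, n_datasets=n_datasets, seed=seed)


def generate_reference_datasets(scenario: GroundTruthScenario) -> list[SummaryDataset]:
    """Simulate the ground-truth population; one summary per repetition.

    Each dataset plays the role of one observed run of the experiment, so
    fitting and reproducibility scoring can be exercised fully offline
    against known ground truth.
    """
    protocol = load_protocol(scenario.protocol_name)
    return run_population(protocol, scenario.population, scenario.n_datasets,
                          scenario.seed, n_per_group=scenario.n_per_group)


def generate_reference_data(scenario: GroundTruthScenario) -> SummaryDataset:
    """Single observed summary table from one 'true' population run."""
    one = GroundTruthScenario(scenario.protocol_name, scenario.population,
                              n_per_group=scenario.n_per_group,
                              n_datasets=1, seed=scenario.seed)
    return generate_reference_datasets(one)[0]


def simulated_pvalue_sets(protocol: Protocol, population: Population,
                          reps: int, seed: int, n_per_group=None) -> list[list[float]]:
    """Per-repetition lists of the protocol's declared test p-values."""
    names = sorted(protocol.pvalue_names)
    datasets = run_population(protocol, population, reps, seed,
                              n_per_group=n_per_group)
    return [[ds.values[n] for n in names] for ds in datasets]
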