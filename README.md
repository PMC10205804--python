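# corvidsim

Computational models of food-caching behavior in corvids (jays, crows,
nutcrackers), built for simulating and fitting behavioral experiments on
caching, cache recovery and specific satiety.

Food-caching birds hide food at visuospatially distinct sites and later
recover it, relying on memory of *what* they cached *where* and how long
ago (*when*), and adapting their caching strategy to anticipated needs.
`corvidsim` implements a memory-augmented reinforcement-learning account of
this behavior as an event-driven, continuous-time agent — the **plastic
caching model** — together with an explicit mental-time-travel control
model (**planning-by-replay**), three lesioned variants, a protocol
description language for the experiments, and likelihood-free machinery for
fitting bird *populations* to published summary statistics.

## The model in brief

A simulated bird carries, per food type f:

- **Motivation** — stomach s_f ≥ 0 (ds_f/dt = −[s_f>0]/τ_s, +n_f per eaten
  item) and hunger h_f ∈ [0,1] (exponential decay with τ_d while digesting,
  relaxation to 1 with τ_h when the stomach is empty): specific satiety.
- **What-where-when memory** — caching events grow binary synapses from
  tray-feature neurons (appearance + position) onto food neurons in layer 1
  of a 7-layer network; nightly systems consolidation moves each trace one
  layer deeper (dwell times 1,1,1,1,3,8 days), so the *active layer* codes
  the age of a memory: layers 1–7 ↔ ages [0,1), [1,2), [2,3), [3,4),
  [4,7), [7,15), [15,∞) days.  Adaptive readout weights v^(l)_f encode the
  expected freshness of food of that age.
- **Policy** — clipped-linear preferences
  p_eat = σ(v_eat_f h_f + η_eat),
  p_cache = σ(w_{f,x_p} + w_{f,x_a} + v_cache_f h_f + η_cache),
  p_inspect = max_{f,l} σ(φ^(l)_f v^(l)_f + v_inspect_f h_f + η_inspect),
  selected by an attention loop equivalent to preference-proportional
  sampling, with uniform post-action time-outs.
- **Caching plasticity** — a neoHebbian three-factor rule at retrieval:
  Δw = −α_pilfer w (cache gone), −α_degrade w (degraded), +α_fresh p_eat_f
  (1−w) (fresh), plus hunger-gated growth of weights toward 1 while
  h_f > 0.99 at available trays (compensatory caching).

The planning-by-replay control model replaces the plastic weights with an
episodic buffer of tray–hunger–outcome episodes, matched against the
current context and replayed forward to score caching options
(tanh-squashed discounted outcome sum).  Populations are described by
rescaled beta densities over every parameter's admissible interval,
parametrized by location/asymmetry pairs (s_i, d_i); fitting maximizes a
k-nearest-neighbor estimate of the log-likelihood of observed summary
tables with CMA-ES.

## Worked example

Simulate the pilfering experiment: two groups of four birds cache worms in
tray A while tray B is covered; the experimenter secretly moves the
pilfered group's caches from A to B between caching and recovery, twice;
then both trays are offered open.

```python
from corvidsim.fixtures import load_protocol, point_population
from corvidsim.simulator import run_once

protocol = load_protocol("dekort07_exp4")
population = point_population("dekort07_exp4")  # hand-tuned parameters
dataset = run_once(protocol, population, seed=1)
for name, value in dataset.values.items():
    print(f"{name:28s} {value:7.3f}")
```

prints

```
pilfered_caches_A_mean         1.000
pilfered_caches_A_sem          0.408
pilfered_caches_B_mean         7.500
pilfered_caches_B_sem          0.645
control_caches_A_mean          6.000
control_caches_A_sem           1.472
control_caches_B_mean          3.000
control_caches_B_sem           1.155
p_caches_A                     0.017
```

Pilfered birds all but stopped caching in their previously preferred tray A
(1.0 vs 6.0 caches on average; independent-samples t-test p = 0.017),
because each unsuccessful retrieval attempt at A multiplied its caching
weights down — while control birds' successful retrievals strengthened
them.  The same protocol run with a lesioned variant
(`point_population(..., variant="no_plasticity")`) shows no group
difference.

The same interface drives the other fixtures (`clayton03_exp2`:
food-specific degradation with generalization to a new tray;
`specific_satiety`: selective suppression and recovery of appetite), the
command line (`corvidsim simulate`, `corvidsim fit`, `corvidsim
reproduce`, `corvidsim list-protocols`), and fitting:

```python
from corvidsim import Population, FitConfig, fit
from corvidsim.fixtures import (satiety_scenario, generate_reference_data,
                                load_protocol, tuned_parameters, SATIETY_SPACE)

observed = generate_reference_data(satiety_scenario(seed=1))
start = Population(tuned_parameters("specific_satiety"), list(SATIETY_SPACE))
result = fit(start, [(load_protocol("specific_satiety"), observed)], seed=2,
             config=FitConfig(budget_evals=2000, n_per_group=8))
print(result.population.mean(SATIETY_SPACE[0]))  # fitted mean appetite constant
```

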