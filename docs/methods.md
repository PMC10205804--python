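# Methods

`corvidsim` simulates populations of food-caching birds (corvids) as
continuous-time agents and fits population-level parameters to summary
tables of behavioral experiments.  This note records the model, the
numerical choices, and what the shipped synthetic studies do and do not
show.

## Agent model

### State and events

Each simulated bird carries per-food-type motivational variables, an
associative memory of its caching events, plastic caching weights (or, in
the planning-by-replay variant, an episodic replay buffer), and a private
random stream.  Integration is event-based: state changes smoothly in
closed form between events and jumps at events.  Events are the bird's own
actions (eat, cache, retrieve/inspect, other) and the experimenter's
additions/removals of food and trays.  Decision instants are generated by
the post-action time-outs themselves — after each action the bird idles
u ~ U[1, δ_kind] seconds — so there is no tick grid.  No bird events are
simulated while the cage holds neither food nor open trays; only the
continuous dynamics advance.

### Motivational control

Stomach s_f ≥ 0 empties linearly at rate 1/τ_s and jumps by the nutritional
value n_f at eating events.  Hunger h_f ∈ [0, 1] decays exponentially with
the digestion constant τ_d while s_f > 0 and relaxes toward 1 with the
appetite constant τ_h once s_f = 0.  The stomach-empty time t* = s_f·τ_s is
resolved exactly inside each interval.  "Zero" stomach is behavioral: the
emptiness level at which hunger starts rising again.  A maintenance-diet
flag integrates hunger as if s_f > 0 for all foods without simulating
individual eating events.  The caching-modulated policy variant adds drives
c_f ∈ [0, 1] that relax toward 1 with τ_d and drop by c_f·c_0/τ_d per
caching event (clipped at 0 for numerical safety; the multiplicative form
cannot undershoot for c_0/τ_d ≤ 1).

Default parameter ranges (units: minutes unless noted): τ_s ∈ [0.5, 10],
τ_d ∈ [0, 20], τ_h ∈ [50, 300], n_f ∈ [0.1, 1], time-outs δ ∈ [10, 200] s.

### What-where-when memory

Caching events grow counters w̃ from the tray's two feature neurons
(appearance, position — a two-hot code) to food neurons in layer 1 of a
seven-layer network; the binary effective weight is the Heaviside of the
counter with a one-hour encoding delay.  A nightly consolidation tick
(default 20 h after the 08:00 start of day 0, i.e. 04:00; configurable)
moves traces one layer deeper on the schedule 1, 1, 1, 1, 3, 8 days, layer
7 terminal, so the active layer codes the age of the memory:
[0,1), [1,2), [2,3), [3,4), [4,7), [7,15), [15,∞) days.  Traces encoded
less than one hour before a tick are not yet effective and stay in layer 1;
this is the reading of the skip rule that realizes the printed age
intervals when recall happens at the caching time-of-day.  Between ticks
the layer is quantized by nights passed, so a mid-day query can lead the
nominal interval by up to one night — inherent to any nightly-consolidation
code.  Re-caching at a site whose trace sits in a deeper layer deletes that
trace and restarts at layer 1 (one-hot in time).  Inspections decrement the
counters (floor 0) for *all* food types with a trace at the probed
features: the inspection examines the site, and the text indexes the
decrement by (f, x, l) without restricting f.  Readout weights v^(l)_f
start at 1 (naive birds expect fresh food) and move toward the experienced
freshness of successful retrievals by a delta rule with rate α_fresh.

### Decision policy

Preferences are clipped-linear (σ(u) = min(1, max(0, u))):
eat σ(v_eat_f·h_f + η_eat); cache σ(w_{f,x_p} + w_{f,x_a} + v_cache_f·h_f +
η_cache) with the hunger term dropped (unmodulated) or replaced by
v_cache_f·c_f (caching-modulated); inspect max over (f, l) of
σ(φ^(l)_f·v^(l)_f + v_inspect_f·h_f + η_inspect) with the derived
v_inspect_f = s_inspect·v_eat_f.  "Other" competes as one uniformly
drawable candidate with constant preference p_other (this matches the
1 + n_f + n_f·n_x + n_x action count).  Selection attends to a uniformly
random candidate and accepts it when its preference exceeds a fresh
U[0, 1] threshold, giving exactly preference-proportional sampling.  If
every preference is zero the loop cannot terminate; after 10× the number of
candidates the "other" action is forced with the draw flagged as
degenerate.

### Caching plasticity (plastic caching model)

At a retrieval that recalls food f at tray x, both feature weights update
as a three-factor rule: Δw = −α_pilfer·w (cache gone), −α_degrade·w
(degraded item), +α_fresh·p_eat_f·(1−w) (fresh item).  Eligibility is the
memory reactivation itself: retrievals from trays the bird never cached in
(no recall) update nothing.  When the outcome is an actual item, the
update applies to the retrieved item's food type (if recalled); a pilfered
outcome applies to every recalled food type at that site.  Because both
feature weights update and the caching preference sums them, the effective
learning rate is doubled relative to a single-feature model.  Separately,
while h_f > θ_hungry = 0.99 and a tray is perceived, its feature weights
relax toward 1 with time constant τ_hungry (compensatory caching); the
gated time is accumulated exactly from the closed-form hunger pieces.
α_reward (range [0, 0.9]) is carried in the parameter set with a
configuration hook but enters no update by default: it appears in no
displayed rule, and guessing its role would be worse than leaving it
inert.

### Planning-by-replay (control model)

Tray interactions are grouped into memory items (same item while
consecutive interactions are < 1 h apart); each item holds
(tray, hunger-vector, outcome) triples with outcomes pilfered / fresh /
degraded / not_inspected.  A caching interaction never overwrites a
retrieval outcome already stored for the same tray in the current item; a
tray perceived but never inspected is recorded as not_inspected when it is
removed.  Before caching, the last three items are matched against every
earlier position by exact tray-sequence agreement (items of different
lengths count as non-matches; offsets reaching before the start of history
contribute zero — the only truncation that keeps the argmax defined).  The
best positions are replayed forward up to six items; matching-tray triples
contribute α_hunger·h + α_fresh·[h ≤ θ][fresh] − α_degrade·[degraded] −
α_pilfer·[pilfered], discounted by γ per item and weighted by a context
similarity.  The similarity formula is implemented exactly as printed,
where outcome *agreement* adds to the penalty term — almost surely a sign
slip in the source, so the flag `similarity_outcome_sign` offers
`agreement_rewards` as the intuitive alternative, with `as_printed` the
default rather than a silent correction.  θ in the fresh term defaults to
θ_hungry = 0.99 (the source leaves it unspecified); tanh of the summed
weight replaces the two caching-weight terms in the caching preference.
All other components are shared unchanged with the plastic caching model.

### Lesioned variants

`no_plasticity` holds the caching weights at zero inside the caching
preference (memory and readout learning stay active);
`no_plasticity_no_memory` additionally holds the memory activations at
zero; `no_plasticity_no_memory_no_motivation` additionally holds hunger at
zero, leaving constant preferences σ(η_eat), σ(η_cache), σ(η_inspect).

## Protocols and summary data

Protocols are programs over three object types (food, trays, inspection
observers) and eleven actions (add, remove, cover, uncover, degrade,
pilfer, four counting queries, wait).  Degrade sets freshness to exactly 0
and leaves the item encounterable; pilfer empties the tray; both happen out
of sight and may act on trays currently outside the cage (trays persist
with their caches across remove/add cycles).  Full control flow is written
as host-language functions against the session interface; the linear
fixtures ship as declarative YAML that round-trips (serialize → re-parse →
identical execution under a fixed seed).  A run fills a declared
measurement schema — per-group means and SEMs of recorded per-bird
quantities plus p-values of declared tests (paired t, independent t, exact
sign/binomial, one-way ANOVA; degenerate inputs yield p = 1 rather than
NaN).  Summary datasets export to CSV with columns (experiment, group,
quantity_name, value, is_pvalue).

A retrieved fresh item re-enters the perceived food pool (it can be eaten
or re-cached — satiety during recovery sessions requires this); a degraded
item is discarded after the feedback.  When several items are cached in a
tray, a retrieve returns one uniformly at random.

## Population fitting

Each fitted bird parameter θ_i ∈ [l_i, u_i] gets a rescaled beta density
with shape parameters softplus(s_i) and softplus(s_i ± d_i) (exponents
f(x) = log(exp(x)+1) − 1 plus one), so d_i = 0 is symmetric and d_i > 0
shifts mass toward the lower bound — the convention fixed here by
quadrature tests.  The likelihood of an observed summary table is
approximated by a k-nearest-neighbor density estimate over K simulated
tables: log p̂ = −d_E·log Δ^(n) + log(n/K) − log V_{d_E}, with the full
estimator normalization so values are comparable across K (the constant is
model-independent for a fixed experiment, so model comparisons are
unaffected).  Distances mix raw quantities with five-level quantized
p-values (bands at 0.001, 0.01, 0.05, 0.1); exact distance ties at zero are
floored at 1e−12 with a warning.

Optimization uses an in-package (μ/μ_w, λ)-CMA-ES.  Within a generation all
candidates are evaluated on common random numbers, which cancels most
simulation noise in the ranking; the generation's best is re-evaluated on
fresh randomness, and K grows (×1.25) when that re-evaluation falls out of
the better half of the generation, shrinking slowly (×0.97) otherwise,
within configurable bounds (default [5, 500]).  The reported point estimate
is the final recombination mean — under a noisy objective it is stabler
than the running best — and the final log-likelihood is averaged over
repeated evaluations with its SEM.

Reproducibility scoring calls an experiment repetition successful when all
declared tests fall on the same side of p = 0.05 as the observed values;
the significance of rate differences is assessed with a one-sided normal
proportion test at the least-favorable baseline 0.5.

## Synthetic studies and fixtures

Three protocols are reconstructed from the behavioral literature at the
level of detail the main descriptions support; phase durations not stated
there (session lengths, amounts) are fixture parameters with documented
defaults.  Tray halves (peanut side / cricket side) are modeled as two
trays sharing a position with distinct appearances, and the two foods are
offered with their half-tray in consecutive sub-phases, which is what
confined each food to its half in the apparatus.

The hand-tuned (not fitted) parameters per fixture are chosen once for
plausible action rates — a decision roughly every half minute in active
sessions, caching dominant over eating when birds are moderately hungry
with trays present — and are the conditions under which the mechanism
regressions run: pilfered birds cache less in their pilfered tray than
controls, and birds taught that crickets degrade in three days inspect the
cricket side of a new tray less than the peanut side.

The satiety protocol offers the two-food choice at *three* delays after
pre-feeding (immediately, after a 50-min gap, after a further 150-min gap).
Two post-recovery time points are the minimum that separates the appetite
time constant from the eating preference: with a single delay the
observable is v_eat·h(t) + η at one point of the recovery curve, so v_eat
and τ_h trade off along an exact ridge, whereas the ratio of recoveries at
two delays pins τ_h independently of v_eat.

The synthetic reference generator simulates a known ground-truth population
("true" hyperparameters deliberately off-center so a fit cannot succeed by
staying at its starting point) and emits one summary table per repetition.
The recovery study treats 1000 such tables as independent observed
replications and maximizes the sum of their per-replication k-NN
log-likelihoods (computed with one vectorized distance matrix) — the
replicated-data maximum-likelihood analogue of fitting a single published
table.  Fitting a *mean* table instead is attractive but wrong: the k-NN
density at an atypically noise-free average rewards populations that
collapse their spread rather than match the truth.  The study fits the
four hyperparameter pairs of the appetite time constant, the two eating
preferences and the eating bias, with the remaining parameters held at
their known values; recovering all ~20 population parameters of the full
model from one small experiment would be hopeless at desk scale and is not
claimed.  The 2000-evaluation CMA-ES budget is spent in two phases — 500
evaluations at K = 16 to localize, then 1500 at K = 64 — because the
objective's shallow ridge directions only acquire a slope exceeding the
evaluation noise at larger K.

What these synthetic studies do *not* show: the generator emulates the
experiments' structure, not real birds.  Passing tests demonstrate internal
consistency (the machinery can find populations it itself generated, and
the mechanisms produce the published effect directions), not that the
parameter values or effect sizes match any real population.  Fitting real
summary tables requires importing them through the CSV schema.

## Numerical choices

- All times in minutes; time-outs converted from seconds at event time.
- Closed-form propagation is exact, so oracle tests integrate the same
  dynamics with an independent dense-grid scheme (split-step Heun at
  dt = 0.01 min for motivation, dt = 0.1 s for gated weight growth).  The
  equivalence checks sample the digestion constant from [3, 20] min: below
  that, a fixed-step explicit scheme at dt = 0.01 min is itself inaccurate
  (stiff limit), while the closed form remains exact by construction.
- Test statistics on degenerate data (zero variance at tiny N) report
  p = 1.0.
- The first decision instant of a wait is drawn like an "other" time-out;
  an all-zero candidate set forces "other" after 10×(candidate count)
  rejection rounds.
- Seeds: every public entry point takes an integer seed; per-bird streams
  are spawned from it, and derived seeds stay below 2^31.

## Known limitations

- No spatial movement, gaze or visual attention; objects are perceived as
  neural codes.
- Loose food is always fresh (degraded items are discarded on retrieval),
  and maintenance diet is a cage flag, not items.
- The nightly consolidation code quantizes memory age by nights passed;
  experiments probing sub-day retention structure would need a finer
  schedule.
- The adaptive-K noise handling is a simplified schedule, not the full
  uncertainty-handling machinery of reference CMA-ES implementations; it is
  pluggable behind `FitConfig`.
- Joint fits share one hyperparameter vector across protocols but assume
  independent bird samples per experiment; only protocol series explicitly
  marked as persistent reuse birds.
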