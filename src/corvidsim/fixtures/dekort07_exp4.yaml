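# Pilfering experiment: two groups cache worms in tray A (tray B covered);
# overnight the experimenter moves the pilfered group's caches from A to B.
# After two such training trials both trays are offered open: pilfered birds
# should cache less in their previously preferred tray A than controls.
# Days start at 08:00; sessions last 15 min; clock in minutes.
name: dekort07_exp4
foods: [mealworm]
groups:
  pilfered: 4
  control: 4
trays:
  A: {appearance: 1, position: 1}
  B: {appearance: 2, position: 2}
steps:
  # --- training trial 1: caching day ---
  - {action: add_tray, tray: A}
  - {action: add_tray, tray: B, open: false}
  - {action: add_food, food: mealworm, amount: 10}
  - {action: wait, minutes: 15}
  - {action: record, what: cached_items, tray: A, as: caches_A_t1}
  - {action: remove_food}
  - {action: move_caches, from: A, to: B, groups: [pilfered]}
  - {action: remove_tray, tray: A}
  - {action: remove_tray, tray: B}
  - {action: wait, minutes: 1425}
  # --- training trial 1: recovery day ---
  - {action: add_tray, tray: A}
  - {action: add_tray, tray: B}
  - {action: wait, minutes: 15}
  - {action: remove_food}
  - {action: pilfer, tray: A}
  - {action: pilfer, tray: B}
  - {action: remove_tray, tray: A}
  - {action: remove_tray, tray: B}
  - {action: wait, minutes: 1425}
  # --- training trial 2: caching day ---
  - {action: add_tray, tray: A}
  - {action: add_tray, tray: B, open: false}
  - {action: add_food, food: mealworm, amount: 10}
  - {action: wait, minutes: 15}
  - {action: record, what: cached_items, tray: A, as: caches_A_t2}
  - {action: remove_food}
  - {action: move_caches, from: A, to: B, groups: [pilfered]}
  - {action: remove_tray, tray: A}
  - {action: remove_tray, tray: B}
  - {action: wait, minutes: 1425}
  # --- training trial 2: recovery day ---
  - {action: add_tray, tray: A}
  - {action: add_tray, tray: B}
  - {action: wait, minutes: 15}
  - {action: remove_food}
  - {action: pilfer, tray: A}
  - {action: pilfer, tray: B}
  - {action: remove_tray, tray: A}
  - {action: remove_tray, tray: B}
  - {action: wait, minutes: 1425}
  # --- final choice: both trays open ---
  - {action: add_tray, tray: A}
  - {action: add_tray, tray: B}
  - {action: add_food, food: mealworm, amount: 10}
  - {action: wait, minutes: 15}
  - {action: record, what: cached_items, tray: A, as: caches_A_final}
  - {action: record, what: cached_items, tray: B, as: caches_B_final}
measurements:
  - {name: pilfered_caches_A_mean, group: pilfered, stat: mean, of: caches_A_final}
  - {name: pilfered_caches_A_sem, group: pilfered, stat: sem, of: caches_A_final}
  - {name: pilfered_caches_B_mean, group: pilfered, stat: mean, of: caches_B_final}
  - {name: pilfered_caches_B_sem, group: pilfered, stat: sem, of: caches_B_final}
  - {name: control_caches_A_mean, group: control, stat: mean, of: caches_A_final}
  - {name: control_caches_A_sem, group: control, stat: sem, of: caches_A_final}
  - {name: control_caches_B_mean, group: control, stat: mean, of: caches_B_final}
  - {name: control_caches_B_sem, group: control, stat: sem, of: caches_B_final}
  - {name: p_caches_A, test: independent_t, of: caches_A_final,
     groups: [pilfered, control]}
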