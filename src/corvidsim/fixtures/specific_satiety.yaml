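# Specific satiety: birds are pre-fed one food to satiety, then offered a
# choice of the pre-fed and a different food; eating of the pre-fed food is
# selectively reduced.  Two further choices after food-free gaps sample the
# appetite-recovery curve at distinct delays -- two time points are needed
# to separate the appetite time constant from the eating preference, which
# otherwise trade off along a ridge.
# No trays: a pure motivational-control design.
name: specific_satiety
foods: [mealworm, peanut]
groups:
  prefed: 8
trays: {}
steps:
  # pre-feeding with mealworms to satiety
  - {action: add_food, food: mealworm, amount: 60}
  - {action: wait, minutes: 20}
  - {action: record, what: eaten, food: mealworm, as: prefed_A}
  - {action: remove_food}
  # immediate two-food choice
  - {action: add_food, food: mealworm, amount: 30}
  - {action: add_food, food: peanut, amount: 30}
  - {action: wait, minutes: 10}
  - {action: record, what: eaten, food: mealworm, as: eat_A_1, minus: [prefed_A]}
  - {action: record, what: eaten, food: peanut, as: eat_B_1}
  - {action: remove_food}
  # short food-free recovery gap
  - {action: wait, minutes: 50}
  # second two-food choice: early point on the recovery curve
  - {action: add_food, food: mealworm, amount: 30}
  - {action: add_food, food: peanut, amount: 30}
  - {action: wait, minutes: 10}
  - {action: record, what: eaten, food: mealworm, as: eat_A_2,
     minus: [prefed_A, eat_A_1]}
  - {action: record, what: eaten, food: peanut, as: eat_B_2, minus: [eat_B_1]}
  - {action: remove_food}
  # long food-free recovery gap
  - {action: wait, minutes: 150}
  # third two-food choice: late point on the recovery curve
  - {action: add_food, food: mealworm, amount: 30}
  - {action: add_food, food: peanut, amount: 30}
  - {action: wait, minutes: 10}
  - {action: record, what: eaten, food: mealworm, as: eat_A_3,
     minus: [prefed_A, eat_A_1, eat_A_2]}
  - {action: record, what: eaten, food: peanut, as: eat_B_3,
     minus: [eat_B_1, eat_B_2]}
  - {action: remove_food}
measurements:
  - {name: prefed_A_mean, group: prefed, stat: mean, of: prefed_A}
  - {name: prefed_A_sem, group: prefed, stat: sem, of: prefed_A}
  - {name: eat_A_1_mean, group: prefed, stat: mean, of: eat_A_1}
  - {name: eat_A_1_sem, group: prefed, stat: sem, of: eat_A_1}
  - {name: eat_B_1_mean, group: prefed, stat: mean, of: eat_B_1}
  - {name: eat_B_1_sem, group: prefed, stat: sem, of: eat_B_1}
  - {name: eat_A_2_mean, group: prefed, stat: mean, of: eat_A_2}
  - {name: eat_A_2_sem, group: prefed, stat: sem, of: eat_A_2}
  - {name: eat_B_2_mean, group: prefed, stat: mean, of: eat_B_2}
  - {name: eat_B_2_sem, group: prefed, stat: sem, of: eat_B_2}
  - {name: eat_A_3_mean, group: prefed, stat: mean, of: eat_A_3}
  - {name: eat_A_3_sem, group: prefed, stat: sem, of: eat_A_3}
  - {name: eat_B_3_mean, group: prefed, stat: mean, of: eat_B_3}
  - {name: eat_B_3_sem, group: prefed, stat: sem, of: eat_B_3}
  - {name: p_satiety, test: paired_t, of: [eat_A_1, eat_B_1], group: prefed}
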