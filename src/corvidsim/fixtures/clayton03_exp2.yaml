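# Food-specific degradation with generalization to a new tray.
# Birds cache peanuts and crickets on days 1-3, in the two halves of a fresh
# tray each day (halves modeled as two trays sharing a position).  Caches of
# day d are recovered on day d+3; the experimenter degrades the crickets of
# the recovered trays, teaching the birds that crickets decay within 3 days.
# On day 6 the bird inspects the (emptied) halves of the day-3 tray: a bird
# that generalizes searches less on the cricket side than on the peanut side.
name: clayton03_exp2
foods: [peanut, cricket]
groups:
  degrade: 4
trays:
  p1: {appearance: 11, position: 1}
  c1: {appearance: 12, position: 1}
  p2: {appearance: 21, position: 2}
  c2: {appearance: 22, position: 2}
  p3: {appearance: 31, position: 3}
  c3: {appearance: 32, position: 3}
steps:
  # --- day 1: cache peanuts in half p1, then crickets in half c1 ---
  - {action: add_tray, tray: p1}
  - {action: add_food, food: peanut, amount: 6}
  - {action: wait, minutes: 8}
  - {action: remove_food}
  - {action: remove_tray, tray: p1}
  - {action: add_tray, tray: c1}
  - {action: add_food, food: cricket, amount: 6}
  - {action: wait, minutes: 8}
  - {action: remove_food}
  - {action: remove_tray, tray: c1}
  - {action: wait, minutes: 1424}
  # --- day 2 ---
  - {action: add_tray, tray: p2}
  - {action: add_food, food: peanut, amount: 6}
  - {action: wait, minutes: 8}
  - {action: remove_food}
  - {action: remove_tray, tray: p2}
  - {action: add_tray, tray: c2}
  - {action: add_food, food: cricket, amount: 6}
  - {action: wait, minutes: 8}
  - {action: remove_food}
  - {action: remove_tray, tray: c2}
  - {action: wait, minutes: 1424}
  # --- day 3 ---
  - {action: add_tray, tray: p3}
  - {action: add_food, food: peanut, amount: 6}
  - {action: wait, minutes: 8}
  - {action: remove_food}
  - {action: remove_tray, tray: p3}
  - {action: add_tray, tray: c3}
  - {action: add_food, food: cricket, amount: 6}
  - {action: wait, minutes: 8}
  - {action: remove_food}
  - {action: remove_tray, tray: c3}
  - {action: wait, minutes: 1424}
  # --- day 4: recover day-1 caches; crickets have decayed ---
  - {action: degrade, tray: c1}
  - {action: add_tray, tray: p1}
  - {action: add_tray, tray: c1}
  - {action: wait, minutes: 15}
  - {action: remove_food}
  - {action: remove_tray, tray: p1}
  - {action: remove_tray, tray: c1}
  - {action: wait, minutes: 1425}
  # --- day 5: recover day-2 caches; crickets have decayed ---
  - {action: degrade, tray: c2}
  - {action: add_tray, tray: p2}
  - {action: add_tray, tray: c2}
  - {action: wait, minutes: 15}
  - {action: remove_food}
  - {action: remove_tray, tray: p2}
  - {action: remove_tray, tray: c2}
  - {action: wait, minutes: 1425}
  # --- day 6: inspect the emptied day-3 halves ---
  - {action: pilfer, tray: p3}
  - {action: pilfer, tray: c3}
  - {action: add_observer, name: obs3, trays: [p3, c3]}
  - {action: add_tray, tray: p3}
  - {action: add_tray, tray: c3}
  - {action: wait, minutes: 10}
  - {action: record, what: inspections, observer: obs3, tray: p3, as: insp_peanut}
  - {action: record, what: inspections, observer: obs3, tray: c3, as: insp_cricket}
measurements:
  - {name: insp_peanut_mean, group: degrade, stat: mean, of: insp_peanut}
  - {name: insp_peanut_sem, group: degrade, stat: sem, of: insp_peanut}
  - {name: insp_cricket_mean, group: degrade, stat: mean, of: insp_cricket}
  - {name: insp_cricket_sem, group: degrade, stat: sem, of: insp_cricket}
  - {name: p_insp, test: paired_t, of: [insp_peanut, insp_cricket], group: degrade}
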