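# Default dose constraints for the 25 Gy / 5-fraction short-course protocol.
# Each row: per-protocol (ideal) and variation-acceptable bounds.
# at_least bounds pass at equality; less_than bounds fail at equality.
criteria:
  - {structure: ptv,       metric: V, dose_level_gy: 25.0,  unit: percent, per_protocol: 95, variation: 90, direction: at_least}
  - {structure: ptv,       metric: V, dose_level_gy: 23.75, unit: percent, per_protocol: 99, variation: 95, direction: at_least}
  - {structure: intestine, metric: V, dose_level_gy: 27.5,  unit: cm3,     per_protocol: 1,  variation: 5,  direction: less_than}
  - {structure: colon,     metric: V, dose_level_gy: 27.5,  unit: cm3,     per_protocol: 1,  variation: 5,  direction: less_than}
  - {structure: bladder,   metric: V, dose_level_gy: 25.0,  unit: percent, per_protocol: 50, variation: 60, direction: less_than}
  - {structure: femur_l,   metric: V, dose_level_gy: 25.0,  unit: percent, per_protocol: 5,  variation: 10, direction: less_than}
  - {structure: femur_r,   metric: V, dose_level_gy: 25.0,  unit: percent, per_protocol: 5,  variation: 10, direction: less_than}
  - {structure: perineum,  metric: V, dose_level_gy: 20.0,  unit: percent, per_protocol: 5,  variation: 10, direction: less_than}
  - {structure: perineum,  metric: V, dose_level_gy: 15.0,  unit: percent, per_protocol: 35, variation: 45, direction: less_than}
  - {structure: perineum,  metric: V, dose_level_gy: 10.0,  unit: percent, per_protocol: 50, variation: 65, direction: less_than}
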