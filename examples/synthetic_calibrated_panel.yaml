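# SYNTHETIC calibrated blood-cell panel (not measured values).
# Counts and secretion rates were drawn log-uniformly from physiological
# ranges (seed 0) and rescaled so the summed steady state equals
# 1e10 EVs/ml x 3000 ml plasma. Replace with measured per-cell-type
# values when available; the schema is unchanged.
baseline_rates:
  elimination:
    rate_per_min: 0.099
  uptake:
    rate_per_min: 0.0001667
blood_panel:
- name: red blood cells
  count: 25732286202404.793
  secretion_per_cell_per_hour: 0.07063026609515624
  secretion_per_cell_per_min: 0.0011771711015859374
- name: platelets
  count: 838234895036.6735
  secretion_per_cell_per_hour: 116.48661131532256
  secretion_per_cell_per_min: 1.9414435219220427
- name: monocytes
  count: 4293853803.261803
  secretion_per_cell_per_hour: 9737.243414342192
  secretion_per_cell_per_min: 162.28739023903654
- name: CD4 memory cells
  count: 5309458205.143742
  secretion_per_cell_per_hour: 7011.85286008729
  secretion_per_cell_per_min: 116.86421433478816
tumor:
  diameter_cm: 1.0
  cell_density_per_cm3: 1000000000.0
  secretion_per_cell_per_hour: 65.0
  uptake_multiplier: 1.0
  elimination_multiplier: 1.0
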