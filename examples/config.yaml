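# Example configuration: a quick exploratory profile.
# Any omitted key keeps its package default.

world:
  n_countries: 60
  low_supply_fraction: 0.2

demand:
  other_income_elasticity: 0.25

supply:
  crop_energy_content: 8.0   # GJ per tonne of first-generation energy crop

design:
  n_runs_per_set: 250
  sobol_seed: 1234

targets:
  kcal_threshold: 2635.0
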