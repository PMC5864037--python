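# landbound

Can the world feed itself in 2050, keep global cropland inside the
planetary boundary, and still grow a meaningful amount of first-generation
bioenergy — all at once? `landbound` is a parsimonious, country-level
global land-use simulator built to answer that question by *normative
scenario screening*: instead of extrapolating a handful of storylines, it
samples the joint uncertainty space of 14 demand- and supply-side
parameters with a Sobol sequence, simulates every parameterisation
through 2000–2050, and screens the ensemble against three explicit
targets. It is aimed at land-use and food-systems modellers who want a
fast, fully reproducible scenario-discovery pipeline.

## The model

Each country *i* carries exogenous population and income paths
(SSP2-like growth) and a potential-yield trajectory under two climate
variants. Per-capita meat and milk consumption ramp from group baselines
(groups 1/3/4: high-income, transitioning, developing) toward 2050
endpoints set by group parameters θ, interpolated piecewise-linearly
through calibrated (θ → outcome) anchors and modulated by income
relative to a reference path; a global limit `consL` caps meat at
122.5 + consL and milk at 240 + consL kg cap⁻¹ yr⁻¹. Cereal demand is
food (boosted by `cerealCon` in countries below 2200 kcal cap⁻¹ d⁻¹)
plus feed, `feed = meat · share(t) · FCR(t)`, plus an income-elastic
residual for all other crops in cereal equivalents.

On the supply side, the relative yield gap g = 1 − y/y_pot shrinks each
year by a factor

    1 − κ · (technology + investments · min(1, γᵢ/γ_ref)) / 100

with κ calibrated once so the all-trend run reaches the 5.13 t ha⁻¹
global mean yield in 2050. Degradation removes `croplandDeg·(t−2000)/100`
of gross production. Every year a single global market allocates land:
countries serve domestic demand up to the ceiling
`suitable · (1 − residualNV/100)`, and the residual global deficit is
covered by exporters in descending-yield order (a land-minimising rule);
bioenergy crops take remaining headroom after food.

The three 2050 targets: every country's food-energy supply
≥ 2635 kcal cap⁻¹ d⁻¹; global cropland ≤ 2010 Mha (15% of 13 400 Mha
ice-free land); first-generation bioenergy delivering the
stringent-mitigation pathway (125 EJ × 7% ≈ 9 EJ) with no unmet crop
demand. A `closeness` score (sum of relative shortfalls) ranks
near-misses.

Because no real input data are packaged, a seeded generator emulates the
statistical structure the analysis needs: baseline yield gaps in
0.3–0.9, ~20% of countries below 2200 kcal cap⁻¹ d⁻¹, cropland pinned to
12% of ice-free land, and a 3.1 t ha⁻¹ baseline global mean yield. See
`docs/methods.md` for what the generator does and does not emulate.

## Worked example

```
$ landbound generate-world --n 150 --seed 1 --out world.csv
wrote 150 countries to world.csv (cropland 12.0% of ice-free land)

$ landbound run --world world.csv --n-runs 200 --out runs/
completed 400 runs (0 failed) -> runs/

$ landbound screen --runs runs/ --out report/
tiers (food / +cropland / all three): (6, 0, 0)
closest to all targets: B-00148
wrote 6 files to report/
```

Of 400 runs (200 Sobol points × two experiment sets), 6 meet the food
target, none also stay inside the cropland boundary, and none meet all
three targets — the count collapses as targets stack, which is the
pipeline's central result: generous diets feed every country but push
cropland past the boundary, and only a narrow corner of parameter space
(high technology, lean feed chains, restrained rich-country diets)
approaches all three targets at once. `report/` contains the cropland
and yield trajectory figures (with the 2010 Mha boundary line), the
parameter-setting chart for flagged runs, and machine-readable CSVs;
`runs/runs.jsonl` holds one full record per run. Set A (current-policy
bioenergy, 74 EJ × 3.5% ≈ 2.6 EJ) can never reach the ~9 EJ target, so
only set B runs can meet all three.

The same pipeline is available as a library:

```python
from landbound import generate_world, SamplingDesign, run_experiment, screen

world = generate_world(150, seed=1)
records = run_experiment(world, SamplingDesign(n_runs_per_set=1000))
print(screen(records).counts)
```

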