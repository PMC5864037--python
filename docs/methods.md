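# Methods

## Scope and design

`landbound` couples a demand system, a yield/trade supply system and a
target-evaluation layer into a deterministic annual simulator
(2000–2050 inclusive) over ~150 synthetic countries, wrapped in a
Sobol-sampled Monte Carlo driver. The guiding principle is parsimony:
every mechanism is the simplest form consistent with the calibration
anchors the model must reproduce, so that each anchor is an exact test
rather than an emergent approximation.

## Demand

**Animal products.** Countries belong to consumption groups 1, 3 and 4
(the group labelling deliberately skips 2): high-income/high-consumption,
transitioning, and developing. Group baselines in 2000 are 80/51/22 kg
meat and 200/80/40 kg milk cap⁻¹ yr⁻¹. For each group parameter θ the
2050 endpoint at reference income interpolates the three printed
(θ → outcome) anchors piecewise-linearly — e.g. group-1 meat: θ ∈
{−50, −30, 50} → {70, 82, 121} kg — making all 18 anchors exact and the
curve monotone in θ. The path between 2000 and 2050 is a linear ramp
whose increment is scaled multiplicatively by the country's *income
index*: realised income growth relative to a 2% yr⁻¹ reference path,
clipped to [0.6, 1.4] to keep the modulation plausible. Per-country
heterogeneity enters by scaling the group curve with the ratio of the
country's baseline consumption to the group baseline, which preserves
the year-2000 calibration identity. The global limit caps meat at
122.5 + consL and milk at 240 + consL kg cap⁻¹ yr⁻¹, applied per country
in every year; the milk constant 240 is chosen so the trend setting
(consL = 0) never binds milk at simulated levels while consL = −60
yields the 180 kg cap.

**(1/time) convention.** All rate parameters accrue linearly:
effect(year) = param · (year − 2000)/100. Three independent anchors pin
this convention (degradation 0.05 → 2.5% by 2050; the feed-efficiency
ratio 1 − 0.2·0.5 = 0.90; the cereal boost 0.4 → +20%).

**Cereals and feed.** Food-cereal demand per capita is constant except
for the `cerealCon` boost in countries starting below
2200 kcal cap⁻¹ d⁻¹. Feed demand is meat production × feed share ×
FCR, with FCR(2000) = 10.5 kg cereal-equivalent per kg meat and feed
share 0.25. The FCR is deliberately larger than a pure-cereal feed
ratio: the model's single commodity is *cereal equivalents* (global
production ≈ 5000 Mt in 2000 = 12% of ice-free land × 3.1 t ha⁻¹), so
feed spans all feed crops expressed in that unit; these defaults put
2050 trend feed demand near 1500 Mt. The feed-share gain factor 1.0
makes the maximum `feed_ratio_cap` raise 2050 feed by
(0.25 + 0.1)/0.25 = 1.40, matching the ≈ +39% spread of the printed
feed outcomes. A residual "other crops" demand per capita (solved at
generation, ≈ 500 kg cap⁻¹ yr⁻¹) grows with income with elasticity
0.25, chosen once so aggregate demand growth lands in the
+60–100% range that medium-growth projections span.

**Food energy.** Daily supply is
(cereal·3000 + meat·1900 + milk·600)/365 + other, in kcal cap⁻¹ d⁻¹,
with configurable densities; the per-country "other foods" term is the
fixed baseline residual, so the 2000 identity is exact. Under a global
supply shortfall, importing countries are served pro rata and the cut
is passed through to food-cereal consumption (meat and milk are not
curtailed — feed scarcity does not feed back into herd sizes).

## Supply and trade

**Yield-gap closure.** The relative gap g = 1 − y/y_pot shrinks by the
annual factor 1 − κ(technology + investments·min(1, γᵢ/0.02))/100. Only
the endpoint of this law is observable (the all-trend 2050 global mean
yield of 5.13 t ha⁻¹), so κ is root-found (Brent, bracket [0.01, 3]) on
the reference world once per world; on the packaged reference world
κ ≈ 0.147. With technology = investments = 0 the gap ratio is constant
and yield tracks the potential. The income term makes investment-driven
closure weaker in slow-growing economies, which is why the two yield
parameters have asymmetric low-end outcomes.

**Degradation** multiplies gross production by 1 − croplandDeg·(t/100);
reported global mean yield is *net* production over cropland, consistent
with degradation lowering average yields.

**Trade.** One global market per year. Each country first covers its own
demand up to its ceiling suitable · (1 − residualNV/100) — residualNV is
applied at the country level. The residual global deficit is assigned to
exporters in descending effective-yield order (ties by country id),
which provably minimises the total cropland expansion needed; a
brute-force oracle over all orderings verifies this on small instances.
Cropland contracts freely when demand falls (no abandonment dynamics).
Shortfall remaining when all ceilings bind is recorded as unmet demand.

**Bioenergy.** First-generation bioenergy crop demand grows linearly
from zero to total₂₀₅₀ × share₂₀₅₀ (set A: 74 EJ × 3.5% = 2.59 EJ;
set B: 125 EJ × 7% = 8.75 EJ), converted at 8 GJ t⁻¹. Food demand has
market priority: bioenergy crops occupy only remaining headroom, and any
shortfall is charged to bioenergy first, scaling delivered energy by the
served fraction.

## Targets

Food: min over countries of 2050 supply ≥ 2635 kcal cap⁻¹ d⁻¹ (the
printed threshold is used verbatim; 2350 × 1.12 = 2632 is close but not
identical, and the printed value wins). Cropland: global 2050 cropland
≤ 2010 Mha = 15% × 13 400 Mha. Bioenergy: delivered first-generation
energy ≥ 8.75 EJ *and* zero unmet bioenergy crop demand; the target is
stored as the exact 8.75 EJ that the conventional "9 EJ" rounds to,
since the stringent pathway supplies exactly 8.75 EJ at full delivery
and a literal 9.0 would make the target structurally unmeetable. All
comparisons are inclusive. closeness = Σ max(0, relative shortfall)
over the three targets; it is zero exactly on the jointly-met set and
continuous at each threshold. The boundary check is authoritative at
2050; a trajectory-wide variant is reported alongside.

## Synthetic world generator

The generator emulates the *structure* of the missing inputs, not any
real country: group shares 25/45/30%, incomes, diets, yields and growth
rates drawn uniformly from group-specific ranges chosen to be mutually
consistent with the group-assignment thresholds; population sizes
heavy-tailed (log-normal) and normalised to 6100 M in 2000, with growth
rates set so the expected 2050 world population is ≈ 9.1–9.5 billion.
Baseline food-energy supply is drawn per group, with the group-4 range
stretched so the expected share of countries below 2200 kcal cap⁻¹ d⁻¹
equals the configured 0.2. Baseline yield gaps are drawn inside
[0.3, 0.9] (wider gaps in poorer groups). Potential yields follow a
linear +30% trend to 2050; the higher-warming variant subtracts a
quadratic late-century penalty (8% of baseline by 2050), so the two
variants coincide in 2000 and order strictly afterwards.

Two closed-form rescalings make the baseline exact without distorting
the sampled heterogeneity: the "other crops" scale pins global
production to 12% × 13 400 Mha × 3.1 t ha⁻¹, and a global yield scale
pins total self-sufficient cropland to 12% of ice-free land (hence
baseline global mean yield exactly 3.1). Suitable land is cropland ×
U(1.2, 2.5) — kept deliberately tight so that global capacity genuinely
constrains high-demand futures and the supply side can fail the food
target.

What the generator does *not* emulate: real-country identities or
geography, within-country distribution, trade frictions, non-cereal
crop dynamics, climate variability around the smooth potential-yield
trends, and any correlation structure beyond group membership. Passing
tests therefore demonstrate the pipeline's internal consistency and its
qualitative screening behaviour under realistic magnitudes — not
predictive skill for any actual country.

## Experiment and screening

The 14 parameters are sampled by a scrambled (seeded) Sobol sequence
over the uncertainty hypercube; the same points are reused for both sets
(a flag switches to disjoint blocks). Each run is deterministic; a
failing run is flagged with its error and excluded from screening, never
dropped. Records stream to JSONL with a flat CSV summary, and re-running
an identical design is byte-identical.

Screening tiers are nested by construction: food; food + cropland; all
three. The "closest" run minimises closeness among runs meeting at least
two targets. Narrative tables report each parameter's value, raw range
position, and a qualitative bin computed on the *trend-anchored*
position (min → 0, trend → 0.5, max → 1, binned at thirds), so
"moderate" always means "near current trends" even for parameters whose
trend sits asymmetrically in its range.

## Problem sizes and numerics

Default analysis profile: 150 countries, 2 sets × 1000 Sobol runs —
this package's standard screening resolution (a run takes a few
milliseconds, the full ensemble seconds). κ calibration tolerance 1e-6;
mass-balance identities hold to 1e-6 relative; allocation ties broken
deterministically by country order; all randomness flows through one
seeded generator per world plus the Sobol seed. At a 2 × 1000 ensemble
the food+cropland tier is a rare-corner event (the joint requirement of
near-maximal group-4 consumption, lean feed chains, restrained diets
elsewhere and near-maximal yield growth), so counts of zero at this
resolution are expected and consistent with the sharp-drop behaviour the
screening is designed to expose.

## Known limitations

Single cereal-equivalent commodity; no prices or trade costs; meat and
milk produced domestically (only cereals trade); no second-generation
bioenergy; no pasture, water, nitrogen or biodiversity constraints; the
consumption cap binds immediately rather than phasing in; feed shortage
does not reduce animal production. The demand curves are anchor
interpolations, not econometric fits.
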