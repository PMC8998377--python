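# landrisk

Landscape ecological risk assessment and patch-based land-use change
simulation for gridded categorical land-use data.

Landscape ecologists quantify how land-use change — urban expansion,
deforestation, reservoir construction — translates into ecological risk by
combining landscape-pattern metrics with expert vulnerability weighting, and
then project that risk forward under policy scenarios. `landrisk` implements
that workflow end to end for raster land-use maps (the kind distributed as
30 m national land-cover products): pattern metrics and a gridded risk index,
ordinary-kriging risk surfaces graded by natural breaks, a random-forest
land-expansion model, and a patch-generating cellular automaton driven by
scenario-adjusted demand. A synthetic-landscape generator makes the whole
pipeline runnable and testable without any external data.

## The model

For each land-use class *i* with *nᵢ* patches, class area *Aᵢ* (ha), class
perimeter *Pᵢ* (m) and total landscape area *A* (ha):

- fragmentation  Cᵢ = nᵢ / Aᵢ
- separation   Nᵢ = ½ √(nᵢ/A) · (A/Aᵢ)
- fractal dimension Fᵢ = 2 ln(Pᵢ/4) / ln(Aᵢ), with Pᵢ in m and Aᵢ in m²
- disturbance  Eᵢ = a·Cᵢ + b·Nᵢ + c·Fᵢ, with (a, b, c) = (0.5, 0.3, 0.2)
- loss index   Rᵢ = Eᵢ · Vᵢ, Vᵢ a normalized expert vulnerability rank

The study area is tiled into square evaluation units (3 km default); the risk
index of unit *k* is the area-weighted mixture

  ERIₖ = Σᵢ (A_{ki} / A_k) · Rᵢ,

kriged to a continuous surface and classified into five grades by Jenks
natural breaks.

Future land use is simulated in two stages. A land-expansion analysis (LEAS)
samples cells that changed class between two observed epochs and fits a
random-forest classifier against driver covariates (elevation, slope,
distances to roads/rivers/towns, population, GDP), yielding per-class growth
probability surfaces. A cellular automaton with multi-type random patch seeds
(CARS) then allocates scenario demand: per cell and class the overall
probability combines the growth surface, the neighborhood cover ratio, and a
self-adaptive inertia tracking the gap to demand; candidate classes are drawn
by roulette wheel and admitted against a geometrically decaying threshold,
a binary transition matrix, and a restricted-area mask. Scenarios (natural
development, economic development, ecological protection) are encoded as
conversion-probability multipliers, restricted zones, and Markov-projected
demand.

## Worked example

```python
from landrisk import synthetic_data as sd, leas, cars, scenarios
from landrisk.risk_assessment import assess_risk, landscape_eri

grid, drivers = sd.generate_landscape(sd.cma_mini_spec(seed=7))
rules = sd.default_change_rules(grid.n_unmasked)
epoch2, changed, truth = sd.generate_change(grid, drivers, rules, seed=8)

surface = assess_risk(grid, side_km=0.9)
print(landscape_eri(grid))          # 0.0481
print(len(surface.units))           # 49
print(surface.breakpoints)          # [0.0381 0.0457 0.0511 0.058]

growth = leas.fit_growth_model(grid, epoch2, drivers, seed=9)
for name, spec in [("NDS", scenarios.nds()), ("EDS", scenarios.eds()),
                   ("EPS", scenarios.eps())]:
    g, tm, restricted = scenarios.apply_scenario(
        growth, cars.TransitionMatrix.all_allowed(grid.class_codes()), spec, epoch2)
    demand = scenarios.markov_demand(grid, epoch2, scenario=spec)
    out, audit = cars.simulate(epoch2, g, cars.CAState(demand_ha=demand, seed=10),
                               tm=tm, restricted_mask=restricted)
    print(name, round(out.class_areas_km2()[2], 2), round(landscape_eri(out), 5))
```

On the 200×200 synthetic landscape (36 km², ~74% forest) this prints a
whole-landscape risk index of 0.0481 for the first epoch, 49 evaluation
units with natural-break grade thresholds 0.0381/0.0457/0.0511/0.0580, and
the scenario runs

```
NDS 26.09 0.06474
EDS 25.99 0.06646
EPS 26.3  0.06431
```

i.e. the ecological-protection scenario retains the most forest (26.30 km²
vs 26.09 under natural development and 25.99 under economic development) and
ends with the lowest simulated risk index, while the economic-development
scenario expands construction the most and ends riskiest — the qualitative
ordering this kind of analysis is built to expose. The top-ranked drivers of
construction expansion recovered by the random forest are distance to town,
population and GDP, matching how the synthetic change was programmed.

The same pipeline is scriptable from a shell (`landrisk synth`,
`landrisk risk`, `landrisk simulate`, `landrisk validate`) with one YAML
config; see `landrisk --help`.

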