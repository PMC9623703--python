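# npartition

Nitrogen-partitioning analysis for dairy cows fed fresh pasture plus graded
urea, packaged as a tested, seedable pipeline.

## The problem

Urinary nitrogen from grazing cows is the dominant source of N reaching
waterways in pasture-based dairy catchments. To test mitigation strategies
one needs diets that differ in crude protein (CP) while holding every other
nutrient constant — easy in a mixed ration, hard on pasture. Supplementing a
basal pasture diet with urea (pure non-protein N) achieves exactly that, but
raises two questions this package's analyses answer:

1. **Tolerance** — above what daily urea dose does milk yield fall? Modelled
   as a continuous two-segment ("split-line") regression of milk yield *y*
   (kg/d) on urea dose *x* (g/d) with an estimated breakpoint *c*:

   *y* = β₀ + β₁·min(*x*, *c*) + β₂·max(*x* − *c*, 0)

   fitted by profiling the SSE of the hinge-basis OLS {1, *x*,
   max(*x* − *c*, 0)} over a candidate grid of breakpoints.

2. **Partitioning** — where does the extra N go? Per cow-day in metabolism
   stalls, N intake (pasture DMI × CP%/6.25 + urea × 0.466) is split into
   fecal N (fecal mass × N concentration), milk N (yield × CP%/6.38) and
   urinary N *by difference* (retention assumed negligible), then urinary N
   is regressed on N intake:

   urine N = α + β · N intake

Because the study's raw data are not deposited, a first-class synthetic
generator reproduces both phases — the 21-day stepped urea acclimation for
15 grazing cows (final doses 0/351/690 g/d, three feedings per day at
≥351 g/d, medium-N starting day 11) and the 10-cow × 7-day total-collection
week (0 vs 250 g/d) — with the fitted models above as ground truth, so every
stage is testable by parameter recovery.

Intended users: animal-nutrition and environmental-modelling researchers who
want a reproducible reference implementation of N-balance-by-difference and
split-line dose-response analysis, or a simulation bench for planning
similar experiments.

## Worked example

```python
import npartition as nv

records = nv.simulate_phase1(nv.SimulationConfig(seed=1))
fit = nv.fit_splitline([r.urea_g for r in records],
                       [r.milk.yield_kg for r in records])
print(fit.breakpoint, nv.decline_per_100g(fit))

balance = nv.balance_table(nv.simulate_phase2(nv.SimulationConfig(seed=1)))
urine = nv.fit_urine_regression(balance)
print(urine.intercept, urine.slope, urine.r2)
```

prints (seed 1):

```
395.0 2.1536466972259833
-119.59519922744545 0.7630116619862863 0.9306361396560562
```

meaning: from 315 simulated grazing cow-days this replicate estimates that
milk yield is unaffected up to ~395 g urea/d and declines ~2.15 kg per
additional 100 g beyond it (true generating values 350 g/d and 2.35 kg);
and from 70 stall cow-days, each extra gram of dietary N adds ~0.76 g to
urine (true slope 0.86), with intake explaining 93% of the variance in
urinary N. The `examples/` scripts walk through each capability
(`python examples/04_milk_dose_response.py`, ...), and the CLI drives the
whole pipeline:

```sh
npartition --seed 1 --out-dir out run-all
```

writing the record CSVs, balance table, fit JSONs, a treatment-comparison
table and a provenance block (config hash, seed, printed-vs-assumed
constants). Equal seeds give byte-identical bundles.

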