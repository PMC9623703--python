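# Methods

## Study design being modelled

Two phases of a urea-supplementation experiment in mid-lactation,
non-pregnant Holstein-Friesian cows on fresh perennial-ryegrass pasture:

- **Phase 1 (grazing, tolerance).** 15 cows, 3 treatments × 5 cows, final
  urea doses 0, 351 and 690 g/d, offered 20 kg DM/d of pasture. Animal
  ethics required a stepped 21-day acclimation: 88 g/d × 4 d, 176 × 3,
  351 × 4, 450 × 3, 600 × 4, 690 × 3, with doses split into two feedings
  per day below 351 g/d and three at or above it. The medium-N group runs
  only the first three steps and starts on day 11, so every group ends the
  window on its final dose. Milk yield is recorded daily; intake is not
  measurable at pasture.
- **Phase 2 (metabolism stalls, N balance).** 10 cows (low-N 0 g/d,
  medium-N reduced to 250 g/d after the phase-1 tolerance finding), total
  collection of feces, urine and milk over days 25–31. Feed offered and
  refused, fecal mass, fecal DM and N concentration, milk yield and
  composition are measured per cow-day.

## Models and procedures

**Split-line dose-response.** Milk yield on urea dose is a continuous
piecewise-linear model with one breakpoint. For a fixed breakpoint c the
model is linear in the hinge basis {1, x, max(x−c, 0)} and is solved by
OLS; the breakpoint is chosen by profiling the SSE over a candidate grid —
by default every 10 g/d across the interior of the observed dose range,
excluding the outermost two distinct doses per side — followed by a ±10 g/d
refinement at 1 g/d resolution. Ties in SSE go to the smallest candidate.
The slope-change p-value is the F-test of the hinge term at the selected
breakpoint (1, n−3 df). Observations are pooled cow-days; cow-level
correlation is deliberately ignored at this stage, which leaves point
estimates unbiased but makes the p-value anticonservative — acceptable for
a tolerance-threshold screen. Grid profiling was chosen over free nonlinear
optimisation because it is deterministic, has no starting-value failure
mode, and the dose design only identifies the breakpoint to grid precision
anyway.

**Energy-balance intake back-calculation (phase 1).** DMI = total ME
requirement / pasture ME, with requirement = maintenance (0.56 MJ/kg
BW^0.75) + activity (0.0037 MJ/kg BW per km walked) + BW-change energy
(OLS slope of BW on day × an energy coefficient) + milk energy. Milk
energy per kg is 0.0929·fat% + 0.0547·CP% + 0.0395·lactose% in Mcal/kg;
the total is divided by a 0.65 lactation efficiency and converted to MJ.
Two deliberate interpretations of the printed formula string: the
"× milk yield" factor multiplies the whole per-kg bracket (the only
dimensionally coherent reading), and the "× 0.238 Mcal/MJ" step is applied
as a *division* by 0.238 (≡ ×4.20 MJ/Mcal), since the bracket is in Mcal
and the other terms in MJ. `EnergyConfig(literal_mcal_conversion=True)`
preserves the literal multiplication for audit. The BW-change coefficient
is not printed anywhere; default 30 MJ/kg (typical ME value of body-tissue
change in dairy cattle), configurable, and irrelevant to phase-2 analyses
where BW is stable and retention assumed zero. No pregnancy term (cows
were not pregnant).

**Nitrogen balance (phase 2).** Per cow-day: DMI = offered − refused;
N intake = DMI·CP%/100·1000/6.25 + urea·0.466; fecal N = fecal mass ×
N concentration (wet basis by default — the reported ~3 g/kg concentrations
alongside ~133 g/d totals imply wet mass; dry-basis input is supported via
the fecal DM%); milk N = yield·CP%/100·1000/6.38; urinary N = intake −
fecal − milk − retention, with retention fixed at 0 (configurable for
sensitivity analysis). The closure identity intake = fecal + milk + urine
therefore holds to machine precision on every row. Negative urine estimates
are flagged and retained, never clipped, so generator or data faults stay
visible. Urine N concentration (g/L) is reported when a urine volume was
recorded; it plays no part in the balance.

**Urinary-N regression.** OLS of estimated urinary N on N intake pooled
over cow-days, unweighted (each point is one cow on one day). Per-cow
aggregation is available but not default.

**Treatment comparison.** Linear mixed model per parameter: fixed treatment
effect, random cow intercept, independent residuals (compound symmetry),
fitted by REML through statsmodels MixedLM. LS means are the fixed-effect
group means; the treatment p-value uses the between-cow denominator df
(n_cows − n_treatments), the conservative animal-as-experimental-unit
convention. For degenerate inputs where REML cannot iterate (zero residual
variance), a closed-form fallback computes LS means from per-cow means,
which is exact for balanced designs. A skewness screen (adjusted
Fisher–Pearson, flag at |skew| > 1 by default, n ≥ 8) stands in for the
normality check.

## Synthetic-data generator

The generator is the package's substitute for the undeposited raw data: it
reproduces the *statistical structure the analysis assumes*, with the
published fitted models as ground truth, so that the estimators can be
validated by parameter recovery at the study's own scale.

- Herd traits: BW ~ N(505, 10.4) kg, DIM ~ N(103, 9.4), BCS ~ N(4.1, 0.04);
  parity uniform 2–6. Cow random intercepts: milk N(0, 1.5 kg/d), urine N
  N(0, 10 g/d), mean zero at herd level.
- Phase 1: milk yield = split-line(urea; 20.5, 0.0029, −0.0235, 350) +
  cow intercept + N(0, 1.5 kg/d) residual. Pasture composition per cow-day
  from the phase-1 means/SDs (CP 20.7 ± 0.56% etc., ME 11.8 ± 0.06).
- Phase 2: offered fixed at 20 kg DM; refusals N(0.9, 0.45) kg clipped to
  [0, offered]; pasture CP 18.4 ± 1.69% (the dominant source of intake
  variation, ~50 g N/d of spread); the implied urinary N is constructed as
  −174.2 + 0.86·intake + cow intercept + N(0, 15 g/d), the non-urinary
  remainder split 0.515 fecal / 0.485 milk (matching the reported ~133 vs
  ~123 g/d means), and fecal N concentration and milk CP% back-solved from
  drawn fecal wet mass N(43.75, 3) kg and milk yield (25.0 / 22.9 kg/d by
  treatment) so the balance module recovers the constructed values exactly.
  Urine volumes N(35.5, 3) L give realistic 8–12 g/L concentrations.
- The urea N fraction (0.466 g N/g, feed-grade standard) and all noise SDs
  are assumptions, not published values — the study reports only treatment
  SEMs. Residual SDs were set once to magnitudes consistent with those SEMs
  (e.g. urine-N SEM 14.2 g/d over 5 cows × 7 d is compatible with a
  ~10 g/d cow SD plus ~15 g/d residual).
- Degenerate draws are clipped with a warning (urine target below 0 at very
  low intake; refusals outside [0, offered]; compositions outside their
  physical ranges).

What the generator does **not** emulate: rumen fermentation or ammonia
kinetics (toxicity appears only as the milk-yield breakpoint), BCS or
pregnancy dynamics, day-to-day autocorrelation within cow beyond the random
intercept, volatile-NH₃ losses from collection containers, and any
covariance between intake level and the urine-line residual. Passing
recovery tests therefore show the estimators are correct for the assumed
error structure, not that the published coefficients are right for real
cows.

## Numerical choices

- Breakpoint ties broken toward the smaller dose; candidate validity
  requires ≥ 2 distinct doses on each side.
- Balance closure asserted to 1e-9 g/d; implausibility flags use the same
  tolerance so float round-off cannot flag a row.
- The mixed model falls back to the balanced closed form only when REML
  fails or returns non-finite estimates.
- CSVs are written with fixed decimal formatting (default 6 places) and a
  versioned header comment; model fits in the pipeline are computed from
  in-memory records, so CSV rounding never touches reported coefficients.
- All randomness flows from a single integer seed per run
  (`numpy.random.default_rng`); phase 2 offsets the seed so the two phases
  draw independent streams.

## Problem sizes

Tests and the acceptance script run the study's own scale: 15 cows × 21 d
(phase 1) and 10 cows × 7 d (phase 2), with 200 seeded replicates for the
recovery checks and ~10,000 rows for the closure property — a few seconds
of compute in total.

## Known limitations

- The urinary-N estimate inherits the by-difference method's assumptions
  (zero retention, perfect fecal/milk measurement); it is not an
  independent measurement, and the regression of it on intake partially
  reuses intake on both sides.
- Reported treatment LS means for urine N cannot be reproduced exactly
  from rounded column means (309/422 vs 307/416 by arithmetic); they derive
  from per-cow-day averaging of unpublished raw data and are covered here
  only qualitatively by the recovery tests.
- No AR(1) or other serial residual structure in the mixed model (v1), and
  no multi-knot or quadratic dose-response alternatives.
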