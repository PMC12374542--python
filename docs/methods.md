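# Methods

## Model

Each EV-secreting cell type is an independent constant source feeding one
well-mixed plasma compartment. Absolute EV counts are tracked, not
concentrations; because every output of interest (percentage contribution,
tEV:nEV ratio, fold changes) is a ratio, plasma volume cancels and is used
only as bookkeeping during panel calibration. Per minute `k`:

```
R_inflow(k) = N_c · S_rc − N_EV(k−1) · (E + U)
N_EV(k)     = N_EV(k−1) + R_inflow(k)
```

Assumptions, stated explicitly:

- **First-order removal.** Elimination (reticuloendothelial clearance) and
  uptake (internalization by recipient cells) are both proportional to the
  circulating count; no saturation, no dose dependence.
- **Constant sources.** Cell counts and per-cell secretion rates do not
  change over the simulated horizon (hours), which is short relative to
  tumor growth or hematopoietic turnover.
- **Well-mixed single compartment.** No tumor-interstitium ↔ plasma
  transfer stage and no spatial effects; every secreted EV enters plasma
  directly. An optional transfer fraction (default 1, i.e. disabled, and
  not derived from any measurement) can scale the tumor secretion rate via
  the population's `secretion_rate` to represent incomplete transfer.
- **Mean-field counts.** Counts are continuous reals; the stochastic
  birth–death variant exists to validate this approximation, and at
  plasma-realistic pool sizes (≥10⁸) relative fluctuations are below 10⁻⁴.
- **Independent cell types.** Populations do not interact; the total pool
  is the sum of per-type steady states.

The recurrence is linear with fixed point `N* = N_c·S_rc/(E+U)` and exact
solution `N_EV(k) = N0·q^k + N*(1−q^k)` with `q = 1−E−U`. The closed form
is implemented in this convex-combination form rather than the algebraically
equal `N* + (N0−N*)q^k`, which loses up to eight digits to cancellation
when `N0` and `N*` differ by many orders of magnitude.

## Parameters

| parameter | default | units | provenance |
|---|---|---|---|
| elimination rate `E` | 0.099 | min⁻¹ | 7-min plasma half-life of small EVs |
| uptake rate `U` | 0.0001667 | min⁻¹ | ≈1 %/hour spontaneous cellular uptake |
| tumor secretion | 65 | EVs/cell/hour | breast-cancer lines in vitro (reported range ~60–65; the simulated value is used) |
| tumor cell density | 10⁹ | cells/cm³ | spherical solid-tumor approximation |
| isolation yields | 1.0 | – | ideal isolation; set <1 to model protocol losses |
| time step | 1 | min | fixed; no sub-stepping (see below) |
| steady-state threshold | 0.99 | fraction of N* | see below |
| horizon | 500 | min | standard sweep horizon |
| plasma volume | 3000 | ml | adult plasma; calibration bookkeeping only |
| total EV pool target | 10¹⁰ | EVs/ml | reported average total blood EV concentration |

`E` is stored as the printed three-significant-figure literature constant,
not recomputed as ln 2/7 = 0.09902 min⁻¹, so that downstream steady states
match published figures digit-for-digit; `halflife_to_rate` remains
available for any other half-life. Rate conversions from per-hour forms are
linear (divide by 60), matching how these constants are reported; at these
magnitudes the continuous-compounding alternative differs in the fifth
digit. In vitro secretion rates likely overestimate in vivo ones, and only
part of tumor-shed EVs reach plasma, so tumor-side outputs are upper-end
estimates.

Scenario multipliers act multiplicatively on the baseline rates: uptake
×{1, 10, 100} (tumor-microenvironment uptake enhancement) and elimination
×{1, 0.1, 0.01} (immune evasion), crossed with diameters {0.5, 1, 2} cm.

## Numerical choices

- **Time step.** The 1-minute explicit step is part of the model
  definition, not a discretization to refine: the closed form quantifies
  its behaviour exactly, and the test suite verifies the recurrence against
  it to 10⁻⁹ relative at every minute.
- **Stability guard.** `E + U ≥ 1 min⁻¹` makes the update overshoot and
  oscillate, so such parameter sets are rejected before iteration
  (`StabilityError`). The largest combination in the default sweep is
  1×E + 100×U ≈ 0.116 min⁻¹, far inside the bound. In a sweep, an unstable
  scenario is recorded as failed and the remaining scenarios run.
- **Time to steady state.** No universal convention exists for when an
  asymptote is "reached"; the package uses the first minute at which the
  trajectory from zero attains 99 % of `N*`, computed in closed form as
  `ceil(ln 0.01 / ln(1−E−U))`. This criterion is scale-invariant (depends
  only on `E+U`), which makes statements like "10× slower elimination →
  10× longer approach" well-defined: with the default constants, 45 min at
  1×E vs 456 min at 0.1×E.
- **Initial condition.** Default `N_EV(0) = 0` (trajectories rise to their
  plateau); configurable.
- **Contribution denominator.** The tumor share is computed against the
  combined pool, `tumor/(tumor+normal)`; the alternative `tumor/normal`
  normalization is exposed and differs by <0.1 % relative at realistic
  magnitudes. The normal pool sums the configured blood panel only — blood
  cells account for ~99 % of plasma EVs, and organ-derived sources are
  excluded by construction.
- **Stochastic oracle.** Integer counts with Poisson(`N_c·S_rc`) births and
  Binomial(`N(k−1)`, `E+U`) deaths per minute. Deaths are drawn on the
  pre-step count, mirroring the deterministic update, so the process mean
  obeys the deterministic recurrence exactly and any discrepancy beyond
  Monte-Carlo error indicates a defect.
- **Sampling tails.** Detection probability is the exact binomial survival
  function; below `p = 10⁻⁶` the Poisson tail is substituted. The
  Barbour–Hall bound (total-variation ≤ `(1−e^{−np})·p ≤ p`) guarantees the
  two branches agree to better than 10⁻⁶ absolute at the switch-over for
  every `n` and threshold. `required_sample_size` brackets from the
  analytic guess `−ln(1−c)/p` and finishes with integer bisection, so the
  returned `n` is tight (`n` meets the confidence, `n−1` does not).
  Sampling is with replacement; the hypergeometric correction at
  `n ≪ 10¹⁰` is negligible and omitted. Cargo detection treats expected
  copies per EV ≤ 1 as a Bernoulli presence probability, with a
  Poisson-per-EV option (`1 − e^{−copies}`) for higher copy numbers.

## Synthetic blood panel

The per-cell-type counts and secretion rates behind the normal-cell EV pool
come from external measurement compilations that are not redistributed
here. The `synthetic_data` module therefore generates labelled-synthetic
panels with the same *structure*: four cell types (red blood cells,
platelets, monocytes, CD4 memory cells) with counts and per-cell secretion
rates drawn log-uniformly from physiological ranges — log-uniform because
counts span five orders of magnitude across types — then rescaled by one
common factor so the summed steady state equals the target total
(10¹⁰ EVs/ml × 3000 ml by default). The ranges are chosen so that at their
midpoints platelets, CD4 memory cells and monocytes dominate the pool and
erythrocytes, despite their enormous count, contribute least per the low
vesiculation of mature red cells — the qualitative ranking reported for
plasma EV origins.

What this emulates: the size and rough composition of the normal plasma EV
pool, enough for every downstream computation (contributions, sweeps,
ratios) to run end to end and for the tumor share to land in the reported
order of magnitude (a 1-cm tumor contributes 0.01–0.1 % for any seed, since
calibration pins the pool total). What it does not emulate: the true
per-type shares (measured secretion rates are not reproduced, only their
ranking), inter-individual variability, or any non-blood-cell EV source.
Passing tests on synthetic panels therefore validate the machinery and the
order-of-magnitude conclusion, not exact published percentages — published
point values like a 0.06 % typical contribution depend on the specific
measured panel and are reproducible only by supplying those measured values
through the config file (`examples/synthetic_calibrated_panel.yaml` shows
the schema and is explicitly labelled synthetic).

## Known limitations

- Uptake enhancement matters more than sometimes assumed: because
  `U ≪ E`, multiplying uptake by 10 moves `N*` by only 1.5 %, but ×100
  brings `U` within a factor of six of `E` and lowers `N*` by 14.3 %
  (= 1 − (E+U)/(E+100U)). "Negligible" is accurate for ×10 and for
  log-scale comparisons, not for ×100 on a linear scale.
- No organ-derived EV sources, lipoprotein misidentification, or platelet
  ex vivo secretion; these raise the effective background in real assays,
  so real tEV fractions are, if anything, lower than modelled.
- No assay error model in the sampling module: detection means "the tEV is
  in the analyzed set", ignoring false positives/negatives of the readout.
- Single compartment: EPR-driven accumulation in the tumor interstitium and
  organ biodistribution are outside scope.
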