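# Methods

## Model overview

The package estimates the social benefit of replacing one school bus
technology with another as the sum of a health term and a climate term.

**Health.** For a bus driven in region *g*, the monetized per-mile impact is

    $ / mile  =  Σ_p  EF_p · Σ_r  D_{g,p,r} · Σ_o  AF_o(ΔC) · M0_o · P_o · V_o

in which `EF_p` is the emission factor (g/mile) of pollutant
p ∈ {primary PM2.5, NOx, SO2, NH3, VOC}, `D` the source-receptor matrix
entry ((μg/m³)/(t/yr)), `AF = 1 − exp(−β·max(ΔC − threshold, 0))` the
attributable fraction under a log-linear concentration–response function,
`M0` the baseline outcome rate, `P` the exposed population and `V` the unit
value (VSL or VSC). Emissions are allocated to cells within a county
proportionally to population, the stand-in for the census-block weighting
used with real data. Benefits are impacts of the replaced bus minus impacts
of the replacement, evaluated on the same receptor set so per-pollutant
decompositions subtract cleanly. Electric buses have zero tailpipe values;
their upstream impact is grid generation (kWh/mi grossed up by 10% charging
and 4.8% transmission losses) times 2.2 attributable deaths/TWh (2018 base)
scaled by projected-year NOx/SO2 intensity ratios, with asthma transferred
from mortality using the asthma:mortality ratio of the diesel side of the
same run rather than a fixed constant.

**Climate.** Diesel CO2 is 10,180 g/gal ÷ 7.36 mpg = 1,383 g/mi. Electric
use-phase CO2 uses the pinned 381 g/mi reference intensity (see *Numerical
conventions*). The lifetime net reduction spreads 190,134 miles uniformly
over 13.5 years (13 full years + one half-weighted year), charges the
battery-production debt (59.5 kg CO2-eq/kWh × 166 kWh = 9.877 t) entirely to
the first year, values each year's net tonnage at a social cost of carbon
interpolated linearly from $228.10/t in 2023 to $281.77/t in 2036, and
discounts at 2%/yr with the first year undiscounted.

## Key parameters

| parameter | default | units | why |
|---|---|---|---|
| asthma CRF slope β | ln(1.33)/6.53 ≈ 0.0437 | per μg/m³ | hazard ratio 1.33 per 6.53 μg/m³ IQR, applied to children 0–17 |
| mortality CRF slope β | 0.008 | per μg/m³ | package-supplied default in the range of the major cohort syntheses; the pooled-cohort (GEMM-style) logistic-weighted log form is available via `gemm_relative_risk` but ships no parameter values |
| CRF threshold | 0 | μg/m³ | no-threshold model |
| asthma incidence | 12.5/1,000 average | per at-risk child/yr | anchored to the national average across child age groups |
| VSL | $9.3M (2014) → $12.4M (2022) | USD | income elasticity 1.0; the shipped income/deflator series are synthetic placeholders calibrated to the published endpoint (combined factor 4/3), since the underlying index values are not part of the package |
| VSC | $610,000 | USD/case | willingness-to-pay per avoided childhood asthma case; no cessation lag |
| cessation lag | 30% yr 1, 50% yrs 2–5, 20% yrs 6–20 | — | mortality response lags an exposure change |
| health discount rate | 3%/yr | — | standard benefit–cost practice; applied to lag and driving years |
| climate discount rate | 2%/yr | — | matches the near-term rate underlying the SCC estimates |
| lifetime | 190,134 mi / 13.5 yr | — | fleet-average service assumption |
| cost differential | $156,000 | USD/bus | lifetime total-cost-of-ownership gap, electric minus new diesel |
| toxicity multiplier | 1 (sensitivity: 5) | — | primary PM2.5 from diesel combustion treated as 5× as toxic by mass in the sensitivity case |

## Synthetic domain

`SyntheticDomainSpec` fully determines a domain (identical specs serialize
to byte-identical fixture bundles). What it emulates, and how:

- **Cells** sit on a jittered lattice over a square (default 240 km). A
  log-normal density field (μ=3, σ=1.1 in ln persons/km²) is amplified near
  a few urban hotspots (amplitude 60, scale 18 km) to create the
  several-orders-of-magnitude urban–rural density contrast the analysis
  turns on. Cell areas shrink where density is high (area ∝ density^−½,
  total area conserved), mimicking variable-resolution air-quality grids.
- **Counties** are contiguous nearest-seed (Voronoi) groups of cells, seeds
  drawn density-weighted so compact urban-core counties exist. Populations
  are integerized by largest-remainder so county totals are exact, then
  split into 16 age bins (three child bins 0–17, 18–24, twelve adult bins
  25+) by fixed national age fractions, again exactly.
- **Urbanization classes**: six ordered labels (large-central-metro …
  noncore) assigned by population-density sextile, at cell and county level.
- **Dispersion**: entry(s,r,p) = k_p·exp(−d²/2L_p²) with L = 5 km for
  primary PM2.5 and 50 km for the secondary species, truncated below 1e-12
  of the self-cell peak and stored sparsely. Kernel peaks (5e-3 (μg/m³)/(t/yr)
  for primary PM2.5, 2e-5–6e-5 for secondary species) were chosen so urban
  marginal damages per ton and the resulting fleet burden rates sit in a
  plausible range for reduced-complexity national models.
- **Emission factors**: anchor sets for MY2005/MY2010/MY2020, a 2017 fleet
  average between them, and an all-zero electric set; the MY2005:MY2010
  ratios are pinned at 12/4/5 for primary PM2.5/NOx/VOC. Other model years
  log-interpolate between anchors with small seeded noise.
- **Baseline rates**: age-increasing adult mortality (0.0013 → 0.084/yr),
  childhood asthma incidence averaging 12.5/1,000 with prevalence 3.5–10.5%
  defining the at-risk pool.
- **Activity**: county VMT ∝ population × 20.7 mi/person/yr (the national
  fleet total over the U.S. population) with mild seeded noise so weighted
  aggregations are non-trivial.

What it does **not** emulate: real geography and meteorology, nonlinear
secondary chemistry (nitrate/ammonium formation is treated as linear, as in
the source-receptor abstraction), demographic spatial correlation beyond
density, cross-domain transport, or census-block within-county structure.
Passing tests therefore validate the pipeline's mathematics and invariants,
not the magnitude of any real county's benefit.

## Numerical conventions

- **Units contract**: SRM entries are (μg/m³)/(t/yr); emission factors in
  g/mile convert via 1e-6 t/g and annual VMT. `apply_srm` refuses fields
  whose unit tag disagrees.
- **Missing sparse entries are exactly zero**; the self-cell entry is the
  row maximum by construction of the monotone kernel.
- **Per-pollutant attribution** applies the attributable fraction channel by
  channel. At marginal exposures (βΔC ≤ 0.01) the channel sum matches the
  joint-field evaluation within 1%; the divergence grows with exposure and
  is a property of the exponential form.
- **Marginal damages per ton** are evaluated by running a literal 1 t/yr
  emission through the full nonlinear pipeline; at that scale the result is
  numerically the linearized product slope × intake × baseline.
- **Cessation-lag discounting**: Σ w_t(1+r)^−(t−1), year-of-exposure share
  undiscounted; 0.9061 at 3%.
- **Driving-year discounting** (health, per-bus): mid-year convention
  (1+r)^−(t−0.5) by default, giving a 13.5-year multiplier of 0.82435 at 3%;
  start-of-year (0.8366) is selectable. Mid-year is the default because it
  reproduces the published per-mile → per-bus pair within the rounding of
  the per-mile input.
- **Climate-side discounting** is start-of-year (first year undiscounted),
  which reproduces the published per-bus climate value under the linear
  SCC schedule.
- **Electric CO2 intensity**: 492 lb/MWh × 1.54 kWh/mi with both losses
  grossing up consumption gives 401 g/mi, not the published 381 g/mi; no
  plausible loss composition recovers it exactly (378–401 g/mi). The
  formula is exposed (`electric_co2_per_mile`) and the published 381 g/mi
  is carried as the pinned reference intensity for lifetime accounting, so
  the discrepancy is visible rather than silently resolved.
- **Largest-remainder rounding** integerizes populations with exact totals;
  ties break by position, keeping generation deterministic.
- **Zero-population counties** error on emission allocation unless the
  uniform-area fallback is explicitly enabled.
- Negative benefits (e.g. a replacement dirtier than the replaced bus, or a
  battery debt exceeding the use-phase gain) are reported, never clipped.

## Design choices

- The mortality CRF defaults to log-linear with configurable age-specific
  slopes. The pooled-cohort logistic-weighted log form is provided as a
  function but not wired in as a default because its parameter values are
  not published inputs of this package; wiring it in requires a baseline
  concentration surface, which the synthetic domain does not model.
- The asthma-to-mortality transfer for grid impacts is computed from the
  diesel side of the same run, keeping the two sides consistent under any
  parameter change.
- District mapping is a weighted crosswalk with per-county weights required
  to sum to 1, making conservation exact by construction.
- Per-mile results are present values at the time the mile is driven;
  per-bus results multiply by lifetime miles and the driving-year
  multiplier. This two-stage definition keeps per-mile values independent
  of the lifetime assumption.
- Class aggregation weights counties by VMT (bus activity), not population;
  with activity proportional to population the two nearly coincide.

## Limitations

- The synthetic kernel is isotropic and stationary; real source-receptor
  relationships are neither. Local-share numbers from the fixture
  (e.g. 99% for primary PM2.5) are upper-end illustrations.
- Ozone, acute exposure, in-cabin exposure and primary PM2.5 from power
  plants are out of scope.
- Cost is a single scalar differential; total-cost-of-ownership variation
  by district, bus size and charging infrastructure is not modeled.
- Test-suite and default problem sizes (≤ a few hundred cells, ≤ a dozen
  counties) were chosen so the whole pipeline runs in seconds; the code
  paths are O(n²) in cells for SRM construction and scale to a few thousand
  cells comfortably.
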