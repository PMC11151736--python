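# stormfate

A desk-scale, process-based simulator for the daily deposition, wash-off,
routing, sorption, decay, and stream delivery of a tire-derived contaminant
(the quinone transformation product of the tire antiozonant 6PPD) in a
gridded urban watershed with explicit storm-sewer infrastructure.

Given a DEM, land-cover and traffic-count grids, a storm-sewer network
table, and a daily weather series, the simulator produces pour-point
concentration time series (ng/L), hotspot maps, and closed daily mass
balances.

## Model overview

* **Deposition** — a per-kilometre tire-wear emission rate (mg km⁻¹ day⁻¹)
  is converted to a per-cell areal rate, multiplied by the tire-content and
  quinone-conversion mass fractions, and scaled per road cell by min–max
  normalised traffic counts. Only road cells *chained upslope of a
  storm-drain inlet* (traversing road cells only) receive deposition; the
  same grid is applied every day.
* **Hydrology** — a minimal daily bucket-and-route scheme: impervious cells
  shed all rain; pervious cells infiltrate into a 4-layer soil column with
  capacity-limited infiltration, fractional percolation above field
  capacity, bottom-layer lateral drainage (baseflow), and a seasonal
  evapotranspiration draw. Surface water follows D8 steepest descent;
  storm-drain inlets intercept everything and deliver the same day to MS4
  outfall cells or to the WWTP (CSS), removing it from the watershed.
* **Contaminant fate** — wash-off of surface mass into locally generated
  runoff (capped by the mass solubility, molar solubility × molar mass);
  advection of the dissolved load with surface routing and pipes;
  equilibrium linear-isotherm partitioning in each soil layer
  (Kd = Koc × foc); aqueous-phase-only vertical/lateral transport; and
  first-order decay of soil pools, modulated below optimal temperature and
  moisture (survival `exp(−k·f_T·f_W)` with
  `f_T = min(1, Q10^((T−25)/10))`, `f_W = min(1, θ/θ_fc)`).
* **Mass balance** — deposition, decay, stream export, WWTP export, and
  storage are reconciled every day to a relative residual ≤ 1e-9; any
  violation aborts the run with the offending date.

All per-cell masses are stored as g/m²; conversions to grams use the cell
area. Default parameters (overridable in the YAML config): emission 100 mg
km⁻¹ day⁻¹, 5 m cells, tire content fraction 0.02, conversion fraction
0.38, calibration scalar 1.0; Koc 11 000 L/kg, molar solubility 1.58e-4
mol/L, molar mass 268.404 g/mol, maximum decay 0.2207475 day⁻¹ (half-life
3.14 days), logKow 2.745 (metadata only).

## Land-cover codes

| code | class            | behaviour                                   |
|------|------------------|---------------------------------------------|
| 1    | road             | impervious; deposition surface when chained |
| 2    | roof             | impervious; water only, no deposition       |
| 3    | other impervious | e.g. parking lots; water only               |
| 4    | pervious         | infiltration, soil column, ET               |
| 5    | stream channel   | conveys water to the pour point             |

## File formats

* Rasters: ESRI ASCII grid (`.asc`), six-line header, row 0 = north.
* Weather CSV: `date, precip_mm, tavg_c` (consecutive days, no gaps).
* Network CSV: `inlet_row, inlet_col, dest_row, dest_col, system_type`
  (`MS4` with an in-grid destination; `CSS` with blank destination → WWTP).
* Config: YAML with sections `deposition`, `contaminant`, `hydrology` plus
  `lc50_threshold`, `random_seed`; every key optional (defaults above).

## CLI

```sh
# write a fully synthetic input bundle (grids, weather, network, config)
stormfate synth --out bundle/ --rows 100 --cols 100 --seed 0

# sanity-check a bundle and report the sewer-network inventory
stormfate validate --inputs bundle/

# run a simulation (omit --inputs to use the default synthetic watershed)
stormfate run --inputs bundle/ --out results/

# summarise a pour-point series: exceedance flags, observed comparison
stormfate report --series results/pour_point.csv --observed
```

`run` writes `pour_point.csv`, `daily.csv`, deposition and hotspot `.asc`
grids, a plain-text mass balance, and a `manifest.json` documenting the
config hash, seed, operator order, and final residuals. Exit codes: 2 for
validation failures, 3 for conservation failures.

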