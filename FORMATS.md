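# File formats

All inputs live in one directory named by `input_dir` in the run config.
Rasters share one grid (row-major, 0-based indices, origin top-left, 10 m
pixels, 0.01 ha each).  Units: masses kg, areas ha, rainfall mm, depth m,
concentrations mg per kg fine earth, bulk density t m⁻³.

## Rasters

ESRI ASCII grid (`.asc`, preferred, portable text) or single-band TIFF
(`.tif`). NoData round-trips as NaN. Required files:

| file | content |
|---|---|
| `elevation.asc` | elevation (m); drives D8 sediment routing |
| `slope.asc` | slope (percent); derived from elevation if absent |
| `conc_n.asc`, `conc_p.asc`, `conc_k.asc`, `conc_soc.asc` | total N, P, K, organic C concentration (mg kg⁻¹) |
| `bulk_density.asc` | bulk density (t m⁻³) |
| `coarse_frag.asc` | coarse-fragment volumetric fraction (0–1) |
| `clay.asc` | clay (percent) |
| `cultivated.asc` | cultivated mask (1 cultivated / 0 not) |

## `households.csv`

`household_id, farm_type, head_age, head_gender, education, labour, income,
livestock, group_membership, transport_access, communication_access, sampled`

`farm_type` is 1 (low), 2 (medium) or 3 (high input intensity);
`head_gender` 1 = male head; `labour` in adult equivalents; `livestock` in
tropical livestock units; booleans as 0/1 or True/False.

## `plots.csv`

`plot_id, household_id, row, col, area_ha, slope, clay, topo_position,
cultivation_period, swc_flag, maize_fraction, legume_fraction,
fallow_fraction, residue_retained_fraction`

`(row, col)` is the seed pixel of the plot footprint; footprints are grown
contiguously to `area_ha / 0.01` pixels on the cultivated mask. Crop
fractions must sum to ≤ 1. Every `household_id` must exist in
`households.csv` (readers reject orphans).

## `coefficients.csv` + `models.csv`

Behavioural models. `coefficients.csv`: `model, predictor, estimate, ci_lo,
ci_hi` with `ci_lo ≤ estimate ≤ ci_hi`. `models.csv`: `model, link,
bound_min, bound_max` with `link` one of `logit`, `log`, `identity`.
Recognised model names: `adopt_fert, qty_fert, adopt_manure, qty_manure,
adopt_legume, share_legume, adopt_swc, yield_maize, yield_legume`.
Predictor names must match columns of the decision context (see
`massai.behaviour.assemble_context`): `const, subsidy, farm_type2,
farm_type3, head_age, head_gender, education, labour, log_income, livestock,
group_membership, transport_access, communication_access, slope, clay,
topo_position, cultivation_period, area_ha, legume_planted, swc_flag,
stock_n, stock_p, stock_k, stock_c, fert_kg_ha, manure_kg_ha,
legume_fraction` (the last three only in yield models).

## `eco_coefficients.csv` (optional)

`name, estimate, lo, hi, units[, description]` — overrides the shipped
ecological defaults (`massai/data/eco_defaults.csv` documents every name).

## `config.yaml`

Keys (all optional, defaults in brackets): `input_dir` [.], `output_dir`
[out], `scenarios` [[current]], `T` [20], `replications` [10], `master_seed`
[42], `progressive` [true], `rain_mm` [900], `depth` [0.10],
`baseline_share` [0.28], `coef_draw` [truncnorm|uniform],
`upscale_target_plots` [null], `record_plot_detail` [false],
`scenario_custom_path` [null]. Unknown keys are rejected.

## Outputs

`records.csv`: long format — `scenario, replication, year, farm_type
(1/2/3/all), variable, value` with per-plot means of `fert_kg_ha,
manure_kg_ha, maize_yield, legume_yield, balance_{n,p,k,c},
stock_{n,p,k,c}`. `plot_detail.csv` (when `record_plot_detail`): per
plot-year-nutrient ledger (`stock_before, stock_after, inflow, outflow,
clipped`). `massai analyze` writes `bands.csv`, `comparisons.csv` and trend
PNGs; `provenance.txt` holds the config hash and master seed.
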