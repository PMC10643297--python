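# Methods

## Scope and state

`massai` simulates a smallholder maize-mixed landscape as a coupled
human–environment system. The unit of account is the cultivated plot, a
contiguous patch of 10 m pixels (0.01 ha each) owned by a household. Plot
state is the nutrient stock vector (N, P, K, SOC in kg ha⁻¹ within the
managed 0–10 cm ridge layer — the depth hand-hoed and fertilised annually),
terrain (slope, clay, topographic position), management (crop allocation,
residue retention, conservation structures) and cultivation age. Household
state is a typology stratum (low / medium / high input intensity) plus
demographics and endowments. The tick is one growing calendar year; there is
no sub-annual dynamics, and rainfall enters as an annual total.

## Mass balance

All ledgers are kept in kg ha⁻¹, so the annual update is the plain sum
`X_{t+1} = X_t + ΣIN − ΣOUT` and conservation is exactly testable. Bulk
density ρ, coarse fragments (as 1 − cf, which reduces fine-earth mass) and
depth D enter only at the concentration↔stock interface,
`stock = conc · ρ · D · (1 − cf) · 10`. Pools floor at zero; the clipped
deficit is logged so `X_{t+1} − X_t − clipped = ΣIN − ΣOUT` holds to
float precision for every plot-year (asserted in the test suite at 10⁻⁹).
Phosphorus and potassium are elemental everywhere inside the model; the
oxide grades P₂O₅/K₂O exist only at the fertilizer-bag interface
(P = 0.436 · P₂O₅, K = 0.830 · K₂O). Each flow pathway carries a fixed
nutrient subset (fertilizer N+P; fixation N; leaching N+K; gaseous N+C;
deposition N+P+K; organic/sediment flows N+P+K+C; crop flows N+P+K) and
violations are rejected at construction.

## Environmental flows

The transfer functions are the standard smallholder nutrient-monitoring
forms, with every coefficient (estimate, lo, hi, units) in an editable CSV:

* **Atmospheric deposition**: `a_X · √rain` per nutrient.
* **Decomposition**: organic additions release `amount · content ·
  first-year availability` per nutrient; carbon is humified into SOC at
  fraction *h*; SOC decays first-order at `k_soc` per year, the decayed C
  leaving on the gaseous pathway.
* **Fixation**: `ndfa · legume biomass · N content`, biomass taken from the
  realised legume yield via the harvest index.
* **Erosion**: multiplicative RUSLE form `R · K · LS(slope) · C · P`, with
  `LS = a + b · slope^e` and the practice factor dropping below one on plots
  with conservation structures; sediment nutrient content is the layer
  concentration times an enrichment ratio.
* **Sediment delivery**: per-pixel losses route one step down the D8
  steepest-descent graph of the elevation raster (strict descent, ties to
  the lowest neighbour index, hence acyclic by construction); the receiving
  pixel collects `sdr` times the routed mass, the rest exports from the
  landscape, so landscape deposition can never exceed erosion. Erosion and
  deposition settle within the same tick.
* **Leaching**: a fraction `clip(l_r · rain/1000 · (1 − l_c · clay/100),
  0, 1)` of the leachable pools — the mineral share of soil N plus
  current-year fertilizer N, and the exchangeable share of soil K (damped by
  a relative factor).
* **Gaseous N**: a bounded fraction (base plus rainfall term) of
  current-year mineral N inputs (fertilizer + mineralised organic N).
* **Crop removal**: grain exports `yield · grain content`; residue biomass
  is `yield · (1/HI − 1)`, the non-retained share leaves with its nutrients
  and the retained share feeds next year's decomposition.

The shipped defaults produce magnitudes of tens of kg ha⁻¹ yr⁻¹ for a
Malawi-like system (e.g. N deposition 4.2 kg ha⁻¹ at 900 mm; soil loss of a
few t ha⁻¹ at moderate slopes) and are deliberately editable placeholders: a
site application must calibrate them. With all coefficients zero and no
farmer action the stocks are provably constant (the null-model identity in
the tests).

## Behavioural models

Each practice is a double hurdle: a logit adoption gate realised by a
Bernoulli draw (so population adoption rates match predicted probabilities
in expectation, rather than thresholding at 0.5), then a bounded GLM
intensity with a log link by default (amounts are positive and
right-skewed; identity is available per model). Evaluation order is legume →
fertilizer → manure → conservation, so the legume indicator exists as a
cross-practice predictor when the fertilizer models run. Conservation
structures persist once built. Yields come from bounded log-link GLMs whose
predictors include the decided inputs, current stocks, cultivation period
and farm type. The subsidy share enters as an ordinary predictor; the
synthetic truth tables give it the hypothesised signs (+ fertilizer,
+ legume, − manure).

Stochasticity between replications is parameter uncertainty: every
coefficient is drawn once per replication from
`Normal(estimate, (hi − lo)/(2·1.96))` truncated to [lo, hi] (uniform
optionally), then held fixed, keeping within-run behaviour coherent. The
estimation counterpart fits the logit by maximum likelihood and the
intensity by a linear model on log amounts (the log-normal intensity GLM),
reporting Wald intervals; perfect separation and undersized samples are
rejected. On synthetic decision data (n = 2000) the intervals cover every
generating coefficient in ≥ 90 % of 50 seeds (acceptance suite).

`winsorise_drift_adjust` implements the prediction-to-baseline correction:
clip predictions to baseline percentiles (default 1st/99th) and rescale by
the drift coefficient mean(baseline)/mean(first-year predictions), computed
on the raw predictions so that a uniformly doubled prediction set has drift
0.5 exactly.

## Population synthesis

A survey sample (e.g. 451 plots representing 17.1 % of cultivated land,
implying round(451/0.171) = 2,637 plots in total) is grown to the full
landscape by stratified resampling: synthetic households copy a sampled row
of the same farm type with continuous attributes jittered by
Normal(0, 0.1 · within-type sd), clipped to the observed within-type range;
farm-type proportions follow the sample by largest-remainder rounding
(within one household). This preserves the empirical joint structure
without distributional assumptions, at the cost of never generating
attribute combinations absent from the sample. Synthetic plots copy a
same-type template and are region-grown as contiguous patches on free
cultivated pixels; sampled households and plots are never altered, no pixel
is assigned twice, and an undersized mask is rejected with the shortfall.

## Scenarios and the engine

Subsidy schedules: current = constant 0.28 (the measured baseline share);
reduced = linear ramp 0.28 → 0.02, whose 20-year mean is exactly 0.15;
zero = baseline in year 0 then 0; universal = constant 0.70. Only the means
are anchored by the policy narrative; trajectory shapes are this package's
choice and fully overridable. Progressive updating advances head age and
per-plot cultivation period each tick (with a hook registry for further
rules, e.g. labour dynamics); everything else is held at baseline so
scenario contrasts isolate the policy effect.

The tick order is fixed: progressive update → decisions → environmental
flows → yields → removal → stock update → record. Decisions must precede
flows (fertilizer feeds leaching and gaseous losses) and removal precedes
the update. Fixation is computed after yields because it needs realised
legume biomass. Fertilizer mass converts to nutrients as an equal-parts
NPK (23-21-0) + urea blend, the usual subsidy package.

Randomness: one `numpy` generator per (scenario, replication), seeded by
`SeedSequence([master_seed, sha256(scenario)[:4], rep])`; all per-plot
draws are vectorised in fixed plot order from that generator. This yields
bitwise determinism for a given config and full stream isolation — a
scenario's results are unchanged by which other scenarios share the batch —
without per-agent generator objects.

## Analysis

Replicate series are smoothed by a centred moving average (default window 3,
shrinking at the series edges; the window is configurable since no canonical
value exists). Bands are per-year means with empirical 5 %/95 % quantiles
across replications. Scenario pairs are compared per year with Welch's
unequal-variance t-test and Bonferroni adjustment `p_adj = min(1, m·p)`
where m counts the whole simultaneous family (years × pairs × variables in
batch mode); a pair differs if any adjusted p < α. Under an
identical-generator null the family-wise error stays within the binomial
envelope of α = 0.05 over 500 repeated comparisons (acceptance suite) —
Bonferroni with Welch tests on 10 replicates is conservative.

## Synthetic data

The generator emulates the structure of the study inputs: elevation as
summed low-frequency harmonics (smooth, realistic slopes), soil property
maps as Gaussian-filtered white noise around configurable means (spatially
autocorrelated, but *not* a digital-soil-mapping product), a cultivated mask
thresholded from a smoothed field, and a 250-household / ~451-plot survey in
three strata whose income, livestock, labour and education rise with input
intensity. Decision data are simulated from the exact double-hurdle process
(log-normal intensity noise, σ = 0.3). What passing tests show is therefore
internal consistency — conservation, determinism, monotonicity, recovery of
known coefficients, calibrated error rates — not predictive validity for any
real landscape: real surveys have measurement error, informative missingness
and behavioural structure (learning, imitation, markets) that the generator
does not emulate.

## Problem sizes and numerical choices

The study-scale configuration used by the tests and the acceptance script is
a 100 × 100 pixel landscape, 250 households (~450 plots), 20 years, 2–3
replications per scenario — chosen as the smallest scale at which every
mechanism (routing, strata, replication statistics) is exercised
meaningfully; it runs in seconds. Tolerances: conservation asserted at
10⁻⁹ kg ha⁻¹; schedule means at 10⁻⁹; stochastic checks use 2–3 σ binomial
envelopes. Degenerate inputs: zero-CI coefficients return the estimate;
zero harvest index disables residue computation; flat terrain routes
nowhere (erosion exports, nothing deposits); empty coefficient tables mean
the practice is never adopted.

## Known limitations

No sub-annual water balance or process-based crop growth; no price or
market feedback of subsidy levels; plot areas and most household endowments
are static by design (progressive hooks are the extension point); the
ecological defaults are order-of-magnitude placeholders pending site
calibration; sediment routing is single-step D8, so multi-pixel cascades
within one year are not represented.
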