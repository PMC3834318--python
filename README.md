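# lakeloads

Estimate summer total-nitrogen and total-phosphorus concentrations in lakes
from stream-network nutrient load predictions.

Watershed load models (SPARROW-style) predict long-term average annual
nutrient fluxes per stream reach, but lake managers care about *summer,
in-lake* concentrations — which are lower, because inputs peak in spring and
lakes retain nutrients in proportion to how long water sits in them.
`lakeloads` implements the full chain from reach predictions to regional
lake assessment:

1. **Network aggregation** — reach loads are summed over an NHDPlus-style
   flow table into per-lake budgets: upstream inputs (total loads of the
   reaches flowing in), incremental inputs (local loads of reaches inside
   the lake), and exports (total loads of the outflow reaches). Flow (CFS)
   converts to m³/yr (× 893,593) and loads to concentrations (mg/L =
   1000 × kg/yr ÷ m³/yr). Lakes whose nitrogen budget does not balance
   (N_in ≠ N_out, indicating diversions) are excluded.
2. **Vollenweider calibration** — nine input-output hypotheses, all
   instances of the generalized mass-balance form

   C_lake = g · C_in · τ^e · z^f / (1 + a · τ^b · z^c · C_in^d)

   with C_in the inflow concentration (mg/L), τ the hydraulic residence
   time (volume/flow, years) and z the mean depth (volume/area, m), are
   fit to observed summer concentrations by robust nonlinear regression
   (Huber IRLS, tuning 1.345, log10 residuals). The null route H0 is an
   ordinary log-log linear adjustment of the export concentration. The
   hypothesis with the lowest AIC wins; a Welch t-test of residual means
   between short (τ < 0.04 yr) and long (τ > 0.4 yr) residence-time lakes
   diagnoses retention bias.
3. **Regional assessment** — the selected model extrapolates to the whole
   lake population: nutrient retention (100·(C_in − C_pred)/C_in), trophic
   state (oligo/meso/eu/hypereutrophic by national-survey thresholds), and
   design-weighted (Horvitz–Thompson) cumulative distributions with 95%
   bands.

A synthetic-data generator (`lakeloads.synth`) produces flow networks,
lognormal reach loads, conic lake morphometry, stratified survey weights
and noisy observations from the calibrated model family, so the entire
pipeline runs and is testable without any external data.

## Worked example

The numbered drivers under `analysis/` run the pipeline on the default
synthetic population of 500 lakes:

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_aggregate.py
python analysis/03_calibrate.py
python analysis/04_extrapolate.py
```

which prints (abridged):

```
aggregated budgets for 494 mass-balanced lakes (494 with defined concentrations)
  median inflow TN 0.654 mg/L, TP 0.0263 mg/L
N: best model H6 (AIC -1512.8 vs H0 -1272.5)
  adjusted R2 0.163 -> 0.489 (+32.7 points), RMSE 0.274 -> 0.214 log10 units
  calibrated coefficients: {'a': 1.894, 'b': 0.359, 'c': 0.312, 'd': 1.128}
residence-time bias (Welch p, short vs long residuals):
  H0/N: p = 1.33e-31
  H6/N: p = 0.652
N: 494 lakes predicted; retention median 40.0% / mean 42.9% (sd 20.5)
```

Reading this: 6 of 500 lakes were dropped for nitrogen mass-balance
violations; among the nine hypotheses the depth- and input-dependent
retention model H6 — the family the observations were generated from, with
true nitrogen coefficients (2.0, 0.38, 0.29, 1.14) — is selected by AIC
and recovers those coefficients; the linear adjustment leaves a strong
residence-time bias in its residuals (p ≈ 10⁻³¹) that the retention model
removes (p ≈ 0.65); and the calibrated model predicts the population's
retention distribution.

The same pipeline is scriptable (`lakeloads all --seed 1 --out results/run`)
and every stage writes CSV plus a `manifest.json` audit trail of lake
counts through each filter.

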