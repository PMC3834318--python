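# Methods

## The mass-balance model family

A completely mixed lake at steady state with conservative inflow loading
obeys C_lake = C_in / (1 + σ·τ), where σ is a first-order loss rate and τ
the hydraulic residence time. The literature's input-output variants differ
in how the loss term depends on τ, mean depth z, and the inflow
concentration itself. All of them fit one generalized form

    C_lake = g · C_in · τ^e · z^f / (1 + a · τ^b · z^c · C_in^d)

which this package uses as the single code path for evaluation and
calibration. The catalog (`lakeloads.models.model_catalog`):

| id | form | free coefficients |
|----|------|-------------------|
| H0 | C_lake = C_out (log-log linear adjustment) | intercept, slope |
| H1 | C_in / (1 + 0.45 τ) | a |
| H2 | C_in / (1 + 1.06) — constant retention | a |
| H3 | C_in / (1 + 5.1 τ / z) — apparent settling velocity | a |
| H4 | C_in / (1 + 1.12 τ^0.53) | a, b |
| H5 | 0.65 C_in / (1 + 0.17 τ) | g, a |
| H6 | C_in / (1 + 3.0 τ^0.25 z^0.58 C_in^0.53) | a, b, c, d |
| H7 | 0.32 C_in τ^−0.18 | g, e |
| H8 | 0.27 C_in τ^−0.22 z^−0.12 | g, e, f |

H2 is implemented exactly as its printed constant-retention form; H3 uses
the τ/z (apparent-settling-velocity) arrangement. Because calibration
refits all free coefficients from these starting values, model selection
is insensitive to either reading. H1–H6 predictions never exceed the
inflow concentration; the product forms H7/H8 can at short τ, and the
resulting negative retentions are reported unclamped.

Calibrated H6 coefficient vectors for northeastern-lake TN and TP are
shipped as presets: `Eq1` = (a, b, c, d) = (2.0, 0.38, 0.29, 1.14) and
`Eq2` = (89.0, 0.40, 0.57, 1.08). These are also the synthetic generator's
default truth.

## Network aggregation

Lakes are sets of reaches sharing a waterbody id on a directed
FromComID→ToComID table. Input reaches are the upstream connections of
internal reaches that are not themselves internal; outflows are internal
reaches with a downstream connection outside the lake — or with none at
all, so a terminal internal reach still exports. Budgets: upstream_in =
Σ total load over inputs; incremental_in = Σ incremental load over
internal reaches; total_in = upstream + incremental; export = Σ total load
over outflows; flow = Σ outflow CFS × 893,593 m³/yr per CFS. Concentration
= 1000 × (kg/yr)/(m³/yr), the exact g/m³ ≡ mg/L identity. Degenerate
cases: zero-flow lakes keep NaN concentrations and are excluded (and
counted) downstream; edges referencing reaches absent from the attribute
table are logged and skipped (network extracts truncate at study-area
borders); a cycle among a lake's internal reaches is an error. The
nitrogen mass-balance filter retains lakes with |N_in − N_out| ≤ 10⁻⁶ ×
N_in — a relative tolerance standing in for the strict-equality criterion,
since aggregation is floating-point.

## Calibration

All fitting is on log10 concentrations. The H0 route is OLS of log10(obs)
on log10(C_out) (statsmodels), back-transformed for predictions. The
Vollenweider routes use iteratively reweighted nonlinear least squares:
each outer iteration solves a weighted Levenberg–Marquardt problem (scipy
`least_squares`) and rederives Huber weights w = min(1, k/|r/s|) with
k = 1.345 and s = 1.4826·MAD of the residuals; convergence when the
largest coefficient step < 10⁻⁸ or after 50 iterations (a huge tuning
constant reduces the procedure to plain nonlinear least squares, which the
tests exploit as an oracle). Multipliers and the H6 exponents are searched
on the log scale to keep them positive; the H7/H8 exponents are
unconstrained in sign. Zero-residual data short-circuit cleanly
(the MAD scale degenerates, weights stay 1).

Goodness of fit: RMSE = √mean((log10 obs − log10 pred)²) from raw
prediction residuals (a switch computes the obs~pred regression's residual
standard error instead, the other plausible reading); adjusted R² is from
the OLS regression of log10(obs) on log10(pred). AIC = n·ln(RSS/n) +
2(p + 1) on the final unweighted log10 residuals with p free coefficients;
the additive constant n·ln(2π) + n is omitted and cannot change rankings.
Selection is argmin AIC over converged fits, ties broken by fewer free
coefficients then lexically. The residence-time diagnostic is a Welch
(unequal-variance) two-sample t-test of residual means between lakes with
τ < 0.04 yr and τ > 0.4 yr — the observed first/fourth quartile bounds,
configurable. The "improvement" of the retention route over the linear
route is reported as percentage points of adjusted R².

Observed TP below the 0.004 mg/L detection limit is replaced by
0.002 mg/L before log transformation (strict inequality: at-limit values
are kept); TN has no below-limit values under the defaults. Hand-selected
reference lakes are included in calibration but excluded from
design-weighted estimates.

## Assessment

The population CDF uses the Horvitz–Thompson weighted proportion
F̂(x) = Σ wᵢ·1[vᵢ ≤ x]/Σ wᵢ with a normal-approximation 95% band from
var̂ = Σ wᵢ²(1[vᵢ ≤ x] − F̂)²/(Σ wᵢ)², clamped to [0, 1]. This is a
deliberate simplification of the survey-package local-mean neighborhood
variance estimator: it needs no spatial coordinates, and the band is used
only as a containment check (fraction of support points where a candidate
CDF lies inside it). Trophic classes use inclusive upper bounds, defaults
TN 0.35/0.75/1.4 mg/L and TP 0.010/0.025/0.050 mg/L per the 2007 national
lake-survey convention (the TP set is configurable; published variants are
inconsistent). Population summaries can filter to survey-comparable lakes
(area ≥ 4 ha, maximum depth ≥ 1 m).

## Synthetic populations

The generator emulates the data structure the analysis assumes, not any
real landscape. Per lake: 1–4 internal reaches in a chain, 0–3 headwater
tributaries joining random internal reaches (so braided inputs occur), one
downstream external reach. Per-unit incremental loads are lognormal
(median 250 kg N/yr, 10 kg P/yr, σ_log = 1), flow is 0.6 CFS per drainage
unit and accumulates additively; nitrogen routes conservatively while
phosphorus decays 10% per internal reach (mirroring a load model that
retains P but not N in lakes). Defaults give median inflow TN ≈ 0.8 mg/L
and TP ≈ 0.03 mg/L. Morphometry: area lognormal (median 30 ha,
σ_log = 1.2), maximum depth lognormal (median 5 m, σ_log = 1.0, floored at
1 m — national surveys span roughly 1–70 m), and volume by the cone
approximation area·z_max/3, standing in for terrain-based volume models
and preserving realistic z:z_max ratios. The resulting residence times
span about 10⁻³–50 yr, well past both bias-test classes. Observations are
the truth model's prediction with N(0, σ²) noise on log10 — σ = 0.21 (TN)
and 0.36 (TP), matching the residual scatter of the calibrated retention
model — so the fitted RMSE reproduces those scales by construction.
Survey design: inclusion probability 0.15/0.30/0.60 by area stratum
(bounds 10 and 50 ha), weight = 1/probability; non-sampled lakes stand in
for hand-selected reference sites. 1.25% of lakes get a planted diversion
(outflow loads scaled by 0.7) to exercise the mass-balance filter,
matching the ~1.2% exclusion rate seen in regional data.

What the generator does *not* emulate: spatial autocorrelation, seasonal
or multi-year dynamics, correlated measurement error, load-model
prediction bias, or real morphometry-load covariance. Passing tests
therefore demonstrate the estimators' correctness and the pipeline's
internal consistency under the stated statistical structure, not accuracy
on any particular real region.

## Problem sizes and numerical choices

The replication studies use 500-lake populations: coefficient recovery
(noise sd 0.1, 20 seeds) yields median relative errors below 10% for all
four H6 coefficients; model selection over all nine hypotheses picks H6
essentially always at the default noise; the Welch contrast gives
p < 10⁻²⁰ for the linear route and p ≈ 0.2–0.9 for the retention route.
All randomness flows from a single integer seed through one NumPy
generator, so datasets and fits are bit-reproducible; the robust fitter is
deterministic given data and starting values (the literature coefficients).
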