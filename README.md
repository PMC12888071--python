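# surveydetect

Tools for comparing wildlife detectability across survey methods —
human point transects (PT), camera traps (CT) and passive acoustic
monitoring (PAM) — built around the question a monitoring programme has
to answer before it spends its budget: *which method, or combination of
methods, detects the target species most reliably per unit of survey
time and money?*

The package is aimed at field ecologists and conservation planners who
have (or want to simulate) timestamped detection events from co-located
survey methods, and need occupancy-model detection probabilities, survey
design comparisons and effort/cost trade-offs out the other end. The
motivating system is a semi-terrestrial, loud-calling forest primate
monitored in forest and open habitats, but nothing in the code is
species-specific.

## What it computes

**Detection histories.** Raw events are collapsed into sites × occasions
matrices over {1, 0, NA}: a sensor occasion is five consecutive recording
days anchored at each device's deployment start, a transect occasion is
one visit. Co-located methods are fused by cell-wise OR with NA
absorption. Naive summaries (rates by method × habitat, latency to first
detection, pairwise overlap, diel activity profiles) come free.

**Occupancy modelling.** The single-season occupancy model with site
covariates on detection,

    L_i = ψ · ∏_j p_ij^{h_ij} (1 − p_ij)^{1 − h_ij} + (1 − ψ) · 1[no detections],
    logit(p_ij) = x_iᵀβ,

with ψ fixable at 1 when presence is known at every site. Candidate
models (null, method, habitat, method × habitat; treatment coding with PT
and forest as references) are fitted by BFGS, ranked by AICc with Akaike
weights, and checked with a MacKenzie–Bailey parametric-bootstrap
chi-square goodness-of-fit test. Detection estimates are back-transformed
with delta-method standard errors, and the minimum number of occasions to
detect an occupying species with 95% confidence is

    N_min = log(0.05) / log(1 − p).

**Survey-time equalization.** Sensor records are repeatedly subsampled
into three equal occasions ≥ 5 days apart whose total length matches a
survey-time window (5 h grid up to 24 days), yielding a detectability
curve with replicate confidence bands, the crossing time against the
point-transect benchmark, and a one-way ANOVA of window-length effects.

**Design economics.** Potential survey area from detection geometry,
campaign cost from per-day personnel and device components, and
post-processing hours per method and annotation mode.

**Synthetic campaigns.** A generator with known ground truth — diel-
structured inhomogeneous-Poisson event streams, recorder battery
dropout, visit scheduling — so the whole pipeline is testable end to end
and parameter recovery is measurable.

## Worked example

One command simulates a campaign (10 locations × 2 habitats, 40 days,
20 transects, 19 cameras, 7 recorders with dropout), builds and fuses
histories, fits and ranks the four candidate models, runs the GOF
bootstrap, equalizes survey time and writes every artifact:

```sh
surveydetect run-study --seed 7 --out results/
```

Selected output from that exact run (`model_table.csv`,
`predictions.csv`):

```
           model  n_params       aicc     delta   weight  parsimonious
          method         7 660.038456  0.000000 0.951905          True
method_x_habitat        14 666.009039  5.970584 0.048095          True
         habitat         2 694.685801 34.647345 0.000000         False
            null         1 694.872565 34.834109 0.000000         False

   method     p    se  n_min
       PT 0.283 0.058  8.992
       CT 0.645 0.039  2.895
      PAM 0.692 0.091  2.542
   CT+PAM 0.804 0.053  1.841
```

The method model carries almost all the AICc weight (the generator gives
each method a different detection probability, so this is the correct
selection); the null model sits ΔAICc ≈ 35 away. Estimated per-occasion
detection is lowest for transects and highest for the fused CT+PAM rows,
so a camera-plus-recorder site would need fewer than 2 occasions
(`n_min` = 1.84) to confirm presence with 95% confidence versus ~9
transect visits. The GOF bootstrap for this run gives p = 0.795 (no
evidence of lack of fit), and the effort curves put the survey time at
which the camera-trap detectability overtakes the transect benchmark at
about 121 h ≈ 5 days (`crossings.json`).

The same stages are available piecewise (`surveydetect simulate`,
`build-history`, `fuse`, `fit`, `effort-curve`, `design`) and as library
functions (`surveydetect.fit`, `rank_models`, `gof_parboot`,
`effort_curve`, …).

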