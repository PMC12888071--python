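# Methods

This note documents the statistical model, the algorithmic and numerical
choices, the synthetic-data generator, and the known limitations of the
package. It states no empirical result beyond what the test suite and
the acceptance script themselves compute.

## The occupancy model

The core is the single-season occupancy model for detection/
non-detection data. Site *i* is occupied with probability ψ; conditional
on occupancy, occasion *j* yields a detection with probability
*p\_ij*. With missing occasions skipped, the site likelihood is

    L_i = ψ · ∏_{j ∈ obs(i)} p_ij^{h_ij} (1 − p_ij)^{1−h_ij}
          + (1 − ψ) · 1[h_ij = 0 ∀j]

Detection is modelled on the logit scale from site-level covariates
(survey method, habitat, optionally their interaction), so *p\_ij* is
constant over occasions within a site. The closure assumption — no
changes in occupancy during the campaign — is inherited from the model
family.

**ψ fixed at 1.** When the species is known to use every sampled
location, ψ is fixed and only detection is estimated; the likelihood
then factorises into independent Bernoulli cells and the intercept-only
MLE has the closed form *detections / non-missing cells*. This closed
form is the oracle the test suite holds the optimizer to (agreement
within 1e-6). ψ can instead be estimated as a single logit-scale scalar
(`psi_mode="free"`); occupancy covariates are out of scope.

**Coding and references.** Covariates are treatment (dummy) coded with
point transects and forest as reference levels, so each method
coefficient is exactly logit(p̂\_method) − logit(p̂\_reference) when the
levels partition the sites. An alternative 2-SD standardisation is
deliberately not the default: the dummy-coded contrasts are the ones
whose arithmetic is directly interpretable against back-transformed
estimates.

**Fitting.** BFGS from a zero start (the likelihood is smooth and
low-dimensional); convergence is declared from the optimizer's own
success flag or an infinity-norm gradient below 1e-4. The covariance is
the inverse observed information from a central-difference Hessian
(step 1e-5). Complete separation — a covariate cohort with all-1 or
all-0 cells — is detected and warned about; its coefficient is not
finite and the fit is still returned. Sites whose rows are entirely
missing are excluded with a warning.

**Model comparison.** AICc = AIC + 2K(K+1)/(n − K − 1) with *n* = number
of sites (not site × occasion cells), the standard bookkeeping for
occupancy designs; it is undefined (explicit error) for n ≤ K + 1.
Ranking reports ΔAICc, Akaike weights and a parsimony flag at the
conventional ΔAICc < 7, plus a check that the null model is excluded
from that band.

**Goodness of fit.** The MacKenzie–Bailey parametric bootstrap. Sites
are grouped into cohorts sharing fitted detection probability and
missingness pattern; within each cohort the observed unique histories
get expected counts *n·P(h)*, cells with expected counts below 2 are
pooled, and the never-observed histories contribute their total expected
mass as a remainder term (the (O−E)²/E term with O = 0 collapses to E).
The statistic is computed on the data, then on `n_boot` datasets
simulated from the fitted model (same design, same NA pattern) and
refitted; the p-value is the proportion of bootstrap statistics at least
as large as the observed one. The seed is mandatory and the whole
procedure is deterministic under it. The default `n_boot` is 1000;
replicates whose refit fails are dropped and counted.

**Minimum effort.** N\_min = log(α)/log(1 − p) with α = 0.05 by default,
returned unrounded; p ∈ {0, 1} is an explicit error. (At a detection
probability printed as 0.329 this formula gives 7.51, not the 7.45
sometimes quoted from rounded intermediates; the function does not chase
printed rounding.)

## Detection histories

Sensor occasions are half-open five-day windows anchored at each
device's own deployment start — devices start on different dates, so a
campaign-wide grid would misalign occasions with device activity.
A cell is 1 if any detected event falls in the window, 0 if the device
was active with no detection, NA if the device covered less than half
the window (battery dropout); the 50% threshold is configurable
(`min_coverage`), since field practice retains partially covered
occasions without a universally agreed rule. Transect histories have one
column per visit; a missed visit is NA, and visits closer than 5 days
warn rather than fail (a protocol deviation, not a data error).
Between-point detections are excluded upstream of ingestion by the
detected flag, not inferred from timestamps.

Fusion matches sites exactly on (location, habitat) — devices are
co-located near the location centre, so no distance matching is needed —
and is a cell-wise OR with NA absorption: 1 beats 0 beats NA. Fusion is
commutative, associative and idempotent (property-tested), and shorter
histories are NA-padded to the longest occasion grid. The stacked
modelling table in which single-method and fused rows coexist reuses the
same underlying observations; the package emits a pseudo-replication
warning when they share locations, and the warning is the honest limit
of what can be done short of a joint model.

All timestamps are timezone-naive local clock time with day boundaries
at 00:00; survey windows (06:00–18:00) are specified in local time, so
this is the only convention that keeps them meaningful.

## Survey-time equalization

Detectability at equalized survey time is estimated by subsampling each
sensor record into 3 occasions of window/3 hours, the end of one
occasion at least 5 days before the start of the next (the stricter
reading of "5 days apart"; start-to-start spacing is available via
`gap_from_start`). Start times are drawn uniformly over the feasible
polytope by an exact order-statistics construction: subtracting
k·(occasion + gap) from the k-th ordered start maps the constrained set
onto ordered triples on the slack interval, so sorting three uniforms
and shifting back samples the uniform distribution exactly, with
deterministic cost (a rejection sampler would sample the same law). Per
replicate, the detectability estimate is the pooled proportion of
detected occasions across sites — equivalent to the ψ = 1 intercept-only
MLE — chosen over per-site averaging for stability at small site counts.
Intervals are 2.5/97.5 percentiles over replicates (default 1000).
Records too short for a window are excluded from that grid point and
reported, mirroring recorders that fail early.

Crossing times against the transect benchmark use linear interpolation
between grid points and return NaN when the level is never reached.
The window-length ANOVA is a hand-computed one-way fixed-effects
decomposition rather than a library call because the degenerate
contracts matter here: all-identical data give F = 0 (SSB = 0), zero
within-group variance with real between-group variation is flagged
`degenerate` with F = ∞; on regular data it agrees with
`scipy.stats.f_oneway` to machine precision (tested).

## The synthetic generator

The generator emulates the motivating campaign: 10 sampling locations ×
{forest, open}, 40 days, 5-day occasions; 20 transects with 3 visits ≥ 5
days apart starting between 06:00 and 18:00; 19 cameras (one open site
unequipped); 7 recorders — three 40-day deployments recording 24–40 days
and four 15-day deployments recording 5–11 days before the batteries
die. Dropout truncates the record tail, matching battery failure rather
than intermittent gaps (configurable).

Occupied sites emit *detected events only* as an inhomogeneous Poisson
process: an hourly base rate λ modulated by a 24-bin diel profile. The
base rate is inverted in closed form from the target per-occasion
detection probability, λ = −ln(1 − p)/occasion-hours, which is exact for
occasions spanning whole days because profiles are normalised to mean
weight 1. Default per-occasion targets are PT 0.33, CT 0.65, PAM 0.79.
Diel shapes are qualitative emulations (no quantitative rate data
exist): crepuscular peaks at 05–07 and 17–19 for the acoustic method, a
05:00–20:00 activity window for cameras, early-morning-weighted visit
detections for transects. Camera and recorder streams at the same site
are independent given occupancy — the simplest null for fusion tests,
and explicitly an assumption: under it the fused occasion-level
detection is 1 − (1−p\_CT)(1−p\_PAM) ≈ 0.9265 at the default targets,
whereas co-located real sensors share animal movement and weather and
will generally fuse to less. No false positives are generated (the
occupancy framework assumes none); a false-positive-rate hook exists and
defaults to 0.

What passing tests on this generator do **not** show about real data:
spatial autocorrelation between neighbouring sites, behavioural
responses to observers, weather-driven covariation between sensors, and
diel rates beyond the assumed shapes are all absent. The generator
validates the machinery (windowing, likelihood, resampling, bookkeeping)
and the estimators' frequentist behaviour under the stated design, not
ecological realism.

## Problem sizes used in the checks

The parameter-recovery check runs 500 simulated campaigns at 30
locations × 2 habitats with every method at every site and no recorder
dropout (60 sites per method; ~180 × 8 and 60 × 3 cells per fit). At
those sizes the per-method Wald intervals on the logit scale are
expected to cover near-nominally, and the check requires empirical
coverage within [0.92, 0.97] and absolute bias below 0.02. Effort-curve
agreement with the Poisson closed form is checked at 100 sites × 300
replicates over a 5-point grid spanning 5 h to 24 days, within 3
conservative Monte-Carlo standard errors (conservative because
replicates share event streams, so the single-replicate variance bounds
the variance of the replicate mean). Goodness-of-fit calibration is
smoke-tested at 40 datasets × 60 bootstrap replicates with a one-sided
bound on the rejection rate, and power is checked on a strongly bimodal
alternative.

## Design economics

Areas: transects cover `points · πr²` with the maximum audible radius
(omnidirectional, as is a single recorder's circle); a camera covers a
circular sector `(angle/360) · πr²`. Internal values are unrounded;
reporting rounds to 2 decimals (the camera sector is 0.01616 ha,
reported as 0.02). Costs are per single site per campaign — transects
pay the full daily rate over 3 field days, sensors a half-day assistant
rate over 2 deployment days plus one device and one battery set (applied
once; whether batteries are replaced mid-deployment is situational and
not modelled). Multi-site campaigns multiply linearly; no bulk
discounts. Post-processing hours are a config lookup with manual and
supervised-automatic modes for the sensor methods; transects have only
manual transcription.

## Known limitations

- Detection covariates are site-level only; occasion-varying covariates
  (weather, observer) are not supported.
- ψ is scalar; no occupancy covariates, no multi-season dynamics, no
  spatial model.
- The stacked single + fused design mirrors established field practice for
  comparability and is pseudo-replicated by construction; the warning is
  informative, not corrective.
- Wald/delta-method uncertainty throughout; no profile likelihood or
  bootstrap intervals for the occupancy fit itself.
- The effort-curve ANOVA treats replicate estimates as independent
  responses; replicates share event streams, so its p-values describe
  the resampling distribution, not fresh field campaigns.
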