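# Methods

This note records the scientific and numerical choices behind
`clamptrace`: what is modelled, what the defaults mean, what the
synthetic data do and do not emulate, and where the design was genuinely
open.

## Protocol and time conventions

Time is in minutes relative to the start of the insulin infusion
(t = 0). Tracers ([6,6-²H₂]-glucose primed 2.0 mg/kg, continuous
0.02 mg·kg⁻¹·min⁻¹; [²H₅]-glycerol primed 0.12 mg/kg, continuous
0.0067 mg·kg⁻¹·min⁻¹) start at t = −120; basal blood samples are drawn
at −30, −20, −10, 0; insulin runs at 10 mU·m⁻²(BSA)·min⁻¹ over 0–120 min
and 40 mU·m⁻²·min⁻¹ over 120–240 min; the glycerol tracer stops just
before the second stage, so glycerol kinetics exist only for the basal
and low-dose windows. Euglycaemia (5 mmol/l) is held by a variable 20%
dextrose infusion spiked with glucose tracer (8 mg/g during stage 1,
10 mg/g during stage 2). Clamp sampling: 30, 60, 90, 100, 110, 120, 150,
180, 210, 220, 230, 240 min. Analysis windows: basal [−30, 0], low-dose
[90, 120], high-dose [210, 240]. Body surface area is Mosteller,
√(height·weight/3600).

The dextrose record is a step function (the pump is adjusted on 5-min
glucose readings); window means of the infusion rate integrate the step
function exactly rather than averaging samples. How bedside adjustments
were logged in the original study is not recorded anywhere, so the
step-function convention is this package's choice.

## Steele kinetics

Single-pool non-steady-state tracer dilution:

    Ra(t)  = [F(t) − V·C(t)·dZ/dt] / Z(t)
    Rd(t)  = Ra(t) − V·dC/dt
    EGP(t) = Ra(t) − GIR(t)

* **V** is a single effective distribution volume, 0.22 l/kg body
  weight, for both glucose and glycerol. No separate pool fraction p is
  applied: whether the original 22% figure already folds in a pool
  fraction is not stated, so `v_frac` is exposed as the single knob and
  0.22 is its definition here.
* **F(t)** for glucose is the pump tracer plus the infusate tracer,
  e_inf(stage)·GIR(t) converted mass→mole (glucose 180.16 g/mol,
  glycerol 92.09 g/mol). The corresponding tracee term uses GIR
  unadjusted; the tracer is ≤ 1% of the infusate mass, and the
  second-order correction is deliberately omitted (it would change GIR
  by < 1%, far below measurement noise).
* **Basal turnover** uses the plateau reduction Ra = F/Z on basal-window
  means of F and Z rather than the non-steady form: the 120-min
  equilibration is designed to end in an isotopic plateau, and a
  derivative estimated from four near-constant samples would only add
  variance. (Whether the original analysis did the same is unstated;
  this choice is recorded here.)
* **Clamp-window rates** are computed at the protocol's sample times
  from the smoothed curves and then averaged over the window
  (compute-then-average, never average-then-compute): the low-dose
  window uses samples 90, 100, 110, 120 and the high-dose window 210,
  220, 230, 240.
* **Stage boundaries.** The 120-min sample coincides with the infusate
  switch and a pump adjustment. A blood sample reflects infusion history
  up to the draw, so kinetics evaluate step functions (pump rate,
  infusate enrichment) and curve slopes as *left* limits at sample
  times. This matters only at t = 120/240; without it the boundary
  sample mixes stage-2 tracer input with stage-1 plasma dynamics and
  biases low-window EGP by several percent.
* **Negative EGP** is reported and flagged (`NEGATIVE_EGP`), never
  floored; flooring is available only as explicit post-processing.

## Smoothing ("optimal segments")

The citation trail for the original smoothing method gives only its
name, so this package implements an explicit, reproducible stand-in
with the same intent: concentrations and enrichments are fitted by
**continuous piecewise polynomials** (degree ≤ 2) whose breakpoints are
restricted to interior sample times, selected by exhaustive search over
knot subsets (≤ 3 extra segments for a 16-point series — at most a few
hundred candidates) minimising a penalised weighted SSE. The fit is
linear in a truncated-power basis, so value continuity is exact while
slope and curvature may jump at breakpoints; genuine kinks at insulin
stage transitions are representable. The default per-parameter penalty
is a small-sample BIC, log(n)·n/(n−p−1): the plain BIC systematically
over-fits a 16-point series once the knot search is free, which deflates
the residual SD and destabilises the dZ/dt term that dominates the
Steele correction. Weights default to uniform; inverse-variance weights
can be supplied when the noise model is known. Derivatives at interior
breakpoints use the right-hand piece by default (the kinetics layer
requests left limits as described above). Evaluation outside the fitted
range raises — tracer slopes must never be extrapolated.

Channel degrees: concentrations default to quadratic segments (the
controller bends them); TTR also defaults to quadratic, with the degree
exposed per channel because a linear TTR fit is a useful robustness
check when noise is high.

## Indices

* **M value** (mg·kg⁻¹·min⁻¹): exact step-function mean of GIR over
  210–240 min minus the glucose-space correction
  (C_end − C_start)·v_space·180.16/Δt, with endpoints taken from the
  measured samples bounding the window. The exact form of the original
  correction (volume used; endpoints vs regression slope) is unstated:
  v_space defaults to the tracer distribution volume (0.22 l/kg) for
  internal consistency, with the classic 0.19 l/kg glucose space as a
  config option, and endpoint differencing is used.
* **M/I**: M over the mean insulin of the same window (pmol/l).
* **Percentage change** 100·(clamp − basal)/basal: positive =
  stimulation (R_d), negative = suppression (EGP, glycerol R_a).
  Undefined (flagged, NaN) when the basal denominator is missing.
  Cohort summaries of the percentage metrics are means of per-subject
  percentages, never percentages of group means — the two differ
  (e.g. group-mean EGP contrasts give −34.7% where the mean of
  per-subject suppressions is −36.4%).
* **AUC**: trapezium rule over the clamp period 0–240 min (basal samples
  excluded by default, switchable); missing interior samples are
  spanned.

## Cohort statistics

Per variable: Shapiro–Wilk at α = 0.05 in *both* groups → pooled-variance
Student t with mean difference and 95% CI; failing that, the same on
log₁₀ values → geometric-mean ratio with back-transformed CI; still
skewed (or non-positive values) → Mann–Whitney U (exact for small
tie-free samples). Contrasts are ordered first group minus/over second.
Associations use Pearson correlation; body-composition adjustment is an
OLS group coefficient with covariates (complete cases — subjects missing
a covariate drop from that model only); effect modification is the
p-value of the product term in outcome ~ predictor + group +
predictor×group. No multiple-testing adjustment is applied anywhere.
Calibration of the whole route-then-test procedure is checked by
simulation (2000 null cohorts at n = 18/15), not assumed.

One inconsistency in the published summaries is deliberately left
uncorrected: the abstract's VAT interval "(−3.30, 0.62)" cannot be a
95% CI for a difference with p = 0.01 (the upper bound's sign is almost
certainly a typo for −0.62); the reconstruction reports what the
printed n/mean/SD imply and flags the discrepancy rather than editing
the source numbers.

## Simulator

State: glucose tracee pool V·C and tracer pool V·C·Z (likewise for
glycerol), integrated by fixed-step RK4 (dt = 0.5 min) from t = −120 to
240 with the pump rate piecewise-constant over 5-min controller blocks.
Cumulative tracer in/out integrals ride along in the state, so the
conservation audit (pool change = in − out) closes to machine precision
and any plumbing error (a lost term, a unit slip) breaks it.

* **Initial condition**: tracer pools start on the basal isotopic
  plateau Z = F/Ra. This emulates a well-primed, fully equilibrated
  tracer; the printed prime (2.0 mg/kg) is ~30% below the ideal prime
  for these kinetics and would leave a slowly drifting basal TTR, which
  the basal plateau estimator (deliberately) does not model.
* **Insulin** is prescribed, not modelled from infusion PK: first-order
  approach (τ = 8 min) to stage plateaus at basal + 2.5 pmol/l per
  mU·m⁻²·min⁻¹ of insulin rate. The increment is calibrated to the
  published scale (M ≈ 4.5 mg·kg⁻¹·min⁻¹ with M/I ≈ 0.030 implies
  high-dose insulin ≈ 150 pmol/l), not to textbook clamp
  pharmacokinetics; the estimator only ever uses measured insulin
  concentrations.
* **Dose–responses**: Hill functions (coefficient 2) of the insulin
  increment above basal; EC50 30 pmol/l for EGP suppression, 60 for
  clearance stimulation, 25 for lipolysis suppression. Each subject's
  curves are anchored to that subject's target suppression/stimulation
  at the stage plateau (suppression capped at 100%). Glucose
  disappearance is clearance × concentration, so disposal responds to
  glycaemia and the closed loop is self-stabilising.
* **Controller**: velocity-form proportional–integral titration on
  5-min true-glucose readings with a 12-min closure horizon, mimicking
  bedside adjustment. Noise-free default runs hold mean |C − 5| ≈ 0.03
  mmol/l over 90–240 min; runs leaving [3, 9] mmol/l are flagged
  UNSTABLE.
* **Noise**: multiplicative Gaussian at sampling — CV 2% glucose, 1.5%
  TTR, 5% insulin, 7% NEFA and glycerol; clipped at zero.
* **Cohort generation**: subject-level anthropometry and physiology are
  drawn from per-group normal (truncated, rejection-counted) or
  log-normal distributions whose means/SDs are the published groups'
  summaries (e.g. basal EGP 8.82 (1.49) vs 9.25 (1.66) µmol·kg⁻¹·min⁻¹;
  VAT 3.72 (1.07) vs 5.68 (2.43) kg). Muscle (R_d stimulation) and
  adipose (lipolysis suppression) sensitivity are drawn from a Gaussian
  copula with per-group correlation 0.25 (BAM) / 0.78 (WEM), adopting
  the published within-group association as a default scenario, not a
  physiological claim.

What the simulator does **not** emulate: meal dynamics,
counter-regulation, NEFA compartment kinetics, insulin PK, assay drift,
between-day variability, the pre-clamp sliding-scale normalisation, and
under-priming of the tracer pools. Passing recovery tests therefore
demonstrates that the estimator is unbiased under its own structural
assumptions at realistic noise — not that those assumptions hold in any
particular real cohort.

## Validation results the code computes

All numbers are recomputed at run time by `scripts/acceptance.py` and
the test suite; none are hard-coded. Problem sizes: the recovery study
uses 200 simulated subjects at default noise (window-mean EGP, R_d,
glycerol R_a bias and RMSE against truth), noise-free recovery of the
percentage indices uses 12 heterogeneous subjects, and statistical
calibration uses 2000 null cohorts at the study's group sizes; these
sizes give Monte-Carlo error comfortably below the thresholds being
checked while keeping a full validation run around a minute.

## Known limitations

* The smoothing stand-in reproduces the intent (penalised optimal
  segmentation), not the exact objective, of the method the original
  analysis cites; window-mean results are insensitive to this by
  design, pointwise derivatives less so.
* Single-pool Steele with constant effective volume is the model the
  study used; no two-compartment or time-varying-volume alternative is
  offered.
* The cohort generator matches printed group-level moments; joint
  distributions beyond the single modelled correlation pair are
  independence assumptions.
* Exact behaviour at the t = 120 boundary sample is convention
  (left limits); other conventions shift low-window EGP by a few
  percent and are not selectable.
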