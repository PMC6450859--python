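# clamptrace

Stable-isotope tracer kinetics for the **two-stage hyperinsulinaemic–
euglycaemic clamp**: Steele non-steady-state glucose and glycerol
turnover with labelled-infusate correction, optimal-segments curve
smoothing, tissue-specific insulin-sensitivity indices, routed two-group
cohort statistics, and an ODE clamp simulator with known ground truth.

## Who this is for

Metabolic physiology groups running clamp studies with
[6,6-²H₂]-glucose and [²H₅]-glycerol tracers who need a reproducible,
tested calculation chain from raw bedside/GC-MS exports (sample times,
concentrations, tracer-to-tracee ratios, pump rates) to the quantities a
clinical paper reports: endogenous glucose production (EGP), peripheral
glucose utilisation (R_d), whole-body lipolysis (glycerol R_a), the M
value and M/I, percentage suppression/stimulation per tissue, AUCs, and
two-group comparison statistics.

## The model

The core is Steele's single-pool non-steady-state equation, modified for
stable isotopes. With plasma tracee concentration *C(t)*, plasma
tracer-to-tracee ratio *Z(t)*, tracer infusion *F(t)* and an effective
distribution volume *V* (22% of body weight):

```
Ra(t) = [F(t) − V·C(t)·dZ/dt] / Z(t)          total rate of appearance
Rd(t) = Ra(t) − V·dC/dt                       rate of disappearance
EGP(t) = Ra(t) − GIR(t)                       endogenous production
```

For glucose, *F(t)* includes the tracer carried by the spiked ("hot")
dextrose infusate (8 mg tracer/g glucose during the low-dose insulin
stage, 10 mg/g during the high-dose stage), which keeps *Z* near
constant and shrinks the non-steady-state correction. Basal turnover
uses the steady-state reduction *Ra = F/Z* on basal-window means, since
the 120-min tracer equilibration ends in an isotopic plateau. *C* and
*Z* are smoothed by continuous piecewise polynomials with breakpoints
selected by an exhaustive penalised-least-squares search before the
derivatives enter the equations.

Tissue-specific insulin sensitivity: **muscle** = % increase of R_d from
basal to the high-dose window (210–240 min), **liver** = % suppression
of EGP from basal to the low-dose window (90–120 min), **adipose** =
% suppression of glycerol R_a from basal to the low-dose window
(suppression reported negative). Whole body: M value (mean dextrose rate
over 210–240 min, glucose-space corrected) and M/I.

Because no subject-level data from the motivating study are available,
the package ships a clamp **simulator**: tracee and tracer pools are
integrated through the full protocol with Hill dose-responses for EGP
suppression, glucose-clearance stimulation and lipolysis suppression,
and a proportional-integral controller that titrates 20% dextrose every
5 min to hold glycaemia at 5 mmol/l. The simulator exposes its full
ground truth, so every estimator stage is validated by parameter
recovery instead of against an unavailable reference dataset.

## Worked example

```python
from clamptrace import Subject, Group, ClampProtocol, analyze_subject
from clamptrace.simulator import SimulationTruth, NoiseModel, simulate_subject

subject = Subject("S001", Group.BAM, weight_kg=90.0, height_cm=175.0)
sim = simulate_subject(subject, ClampProtocol(),
                       SimulationTruth(seed=11), noise=NoiseModel.none())
row = analyze_subject(subject, sim.series)
print(f"basal glucose Ra {row['basal_glucose_ra']:.2f} umol/kg/min")
print(f"clamp EGP        {row['clamp_glucose_ra']:.2f} umol/kg/min")
print(f"clamp Rd         {row['clamp_glucose_rd']:.2f} umol/kg/min")
print(f"M value          {row['m_value']:.2f} mg/kg/min")
print(f"EGP suppression  {row['pct_supp_egp']:.1f} %")
```

prints

```
basal glucose Ra 9.00 umol/kg/min
clamp EGP        5.74 umol/kg/min
clamp Rd         25.65 umol/kg/min
M value          4.29 mg/kg/min
EGP suppression  -36.2 %
```

The simulated subject's true basal EGP is 9.0 µmol·kg⁻¹·min⁻¹ and its
true low-dose EGP is 5.80 (35.6% suppression): the noise-free pipeline
recovers the basal plateau exactly and the non-steady clamp windows to
within ~1 percentage point.

The full study pipeline is laid out as numbered drivers:

```
python analysis/01_simulate_cohort.py      # 18 + 15 subjects -> results/simulated_study/
python analysis/02_fit_tracer_kinetics.py  # per-subject turnover + indices
python analysis/03_compare_groups.py       # routed two-group contrasts, adjustment, interaction
python analysis/04_validate_estimator.py   # recovery study + calibration
```

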