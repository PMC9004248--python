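# Methods

## The circulation model

`hemowave` simulates the systemic and pulmonary circulation as a
closed-loop electrical-analog network with ten compliant compartments
and three inertial branches (13 state variables):

```
LA → mitral → LV → aortic valve (L) → aorta → (R,L) → conduit artery
→ (R,L) → peripheral artery → SVR → systemic veins → RA → tricuspid
→ RV → pulmonary valve → pulmonary artery → PVR → pulmonary veins → LA
```

Pressure and flow are reported at the *peripheral artery* compartment,
the site that corresponds to a radial/femoral arterial line; its inflow
is the co-located flow used for wave separation.

**Heart chambers.** The ventricles follow a time-varying elastance
P(V,t) = P_ed(V) + a(t)·[E_es·(V−V₀) − P_ed(V)], with an exponential
end-diastolic relation P_ed(V) = S·(e^{λ(V−V₀)} − 1) and a double-Hill
activation a(t) = [x₁ⁿ/(1+x₁ⁿ)]·[1/(1+x₂ᵐ)], normalized to unit peak.
The atria are passive elastic chambers.  Two couplings make the beats
respond realistically to the study's deficits:

* the tabulated left-ventricular contractility index (mmHg/ml) maps to
  peak elastance through a power law anchored at the 60-year value,
  E_max = E₆₀·(LVC/E₆₀)^γ with γ = 1.3.  A purely proportional mapping
  cannot depress ejection fraction below ~55% of control even at 30% of
  baseline contractility, because the venous-return feedback lowers
  arterial pressure (and hence end-systolic volume) in step; clinically,
  deep cardiogenic shock roughly quarters the ejection fraction, which
  the power law reproduces (LVEF 0.59 → 0.24 at factor 0.30).
* systolic duration scales with ventricular filling: the activation
  curve is time-dilated per beat by (EDV/145 ml)^0.5, clipped to
  [0.6, 1.35].  This encodes the well-known shortening of left
  ventricular ejection time in hypovolemia ("flow time" as a preload
  index) and its prolongation in the dilated failing ventricle; without
  it, a preload deficit changes only the waveform's scale, not its
  shape.

**Arteries.** The three systemic arterial compartments are
exponential-elastic, P(V) = B·(e^{(V−V₀)/V_s} − 1), so compliance
dV/dP = V_s/(P+B) falls as the vessel distends.  V_s anchors each
segment's compliance at 100 mmHg to its share (45/25/30%) of the
subject's total arterial compliance (the reciprocal of the tabulated
systemic arterial stiffness, which carries the age dependence of the
vascular Young's modulus).  B = 60 mmHg sets the nonlinearity:
hypotensive states see softer, slower-conducting arteries, which is
what makes deficit classes change waveform *morphology* rather than
amplitude alone.  The two inter-segment branches carry resistance and
inertance, producing wave travel, a reflected wave, peripheral
amplification and a dicrotic notch at the measurement site.  The
pulmonary artery, pulmonary veins and systemic veins are linear
compliances.

**Valves** are pressure-gated resistances; the aortic valve
additionally carries an inertance, with retrograde flow clamped to zero
at valve closure.

**Respiration.** Spontaneous breathing adds a sinusoidal pleural
pressure (resting −4 mmHg; peak-to-trough 5 mmHg per liter of tidal
volume; default 11/min, 0.5 l) to all intrathoracic compartments
(heart, aorta, pulmonary vessels).

**Blood-volume bookkeeping.** Unstressed volumes are fixed at the
baseline subject; the blood-volume override rescales every initial
distending pressure by a common factor (solved by bisection so the
compartments sum to the overridden total), after which the dynamics
redistribute volume freely.  Volume changes therefore act on *stressed*
volume, making arterial pressure strongly sensitive to moderate
hemorrhage; a deficit exceeding the total stressed volume (below ~65%
of baseline blood volume) is rejected as unfillable.

**Integration.** Classical RK4 at a fixed 2 kHz internal step,
decimated to exactly 400 Hz output.  The network is conservative by
construction (every flow appears in exactly two volume derivatives), so
total blood volume is constant to round-off (≲1e−12 relative over
60 s).  There are no random numbers anywhere in the model; identical
inputs give bit-identical traces.

## Calibration policy

All internal constants live in `hemowave/data/calibration.yaml`
(version 1) and were fixed once against two kinds of targets, never at
run time:

* the 60-year control operating point — arterial pressure ≈ 140/74
  (MAP 103) mmHg, cardiac output ≈ 5.5 l/min, ejection fraction ≈ 58%,
  central venous pressure ≈ 9 mmHg.  The frozen model gives
  151/79 (MAP 107), 5.5 l/min, 59%, 14 mmHg;
* morphological requirements at the peripheral site — an incisura near
  end-systole followed by a single dicrotic wave, peripheral systolic
  amplification, a notch that sinks with hypovolemia and fades under
  vasodilation, and a stressed-volume reserve that tolerates a 30%
  hemorrhage (the deficit depth the stop rules reach).

The subject presets (`data/subjects.yaml`) are used verbatim; only the
mapping from preset parameters to network elements is calibrated.

## Experiment designs

* **Stepwise reductions**: blood volume in 2% steps of baseline
  (the model, like the circulation it mimics, is most sensitive to this
  knob), contractility and resistance in 5% steps; after every step the
  model is re-run to equilibrium (first beat from which MAP and CO both
  change < 1% per beat over three consecutive beats); iteration stops
  before the first step with DBP < 20, PP < 20 or MAP < 30 mmHg, and
  the violating step is excluded.  At 60 years the frozen model sustains
  −26% blood volume, −75% contractility and −75% resistance.
* **Baroreflex compensation**: the causal knob is first bisected to a
  MAP of 60 ± 1 mmHg; the compensator (HR, LVC or SVR up, venous
  compliance down) then moves in 2%-of-baseline sub-steps until MAP
  reaches 70 mmHg (a final bisection lands within ±1 mmHg) or the cap —
  +100% for increases, −50% for the venous-compliance decrease (a
  100% reduction would be a zero compliance, which is singular).
  Compensating a deficit with its own knob is rejected.
* **Breathing run**: 70 s simulated, features taken from the ~60 s of
  equilibrated beats; per-feature stability is SD/|mean|·100% using the
  population SD.

## Analysis conventions

* Feature-table PCA is z-scored (features mix mmHg, s, mmHg/s and
  dimensionless units); raw-waveform PCA uses beats normalized to the
  unit square (200 samples), so morphology rather than pressure level
  drives the components.  Both keep all components; explained variance
  sums to 100%.
* The "correlation" attached to a PC is the Pearson correlation of each
  input column (time sample or feature) with the PC score vector;
  screening reports |r| > 0.25.  Component signs are fixed by making
  each PC's largest-magnitude correlation positive.
* Sensitivities are signed percent-over-percent ratios; a zero baseline
  feature yields a missing value, never zero.
* Features undefined on a beat (absent diastolic peak, absent anacrotic
  notch) are imputed by the fallback conventions of the fiducial
  detector (value pinned to the dicrotic notch / systolic peak), so
  feature matrices have no holes.
* The Liljestrand–Zander stroke volume (k = 3.5) is a relative
  pulse-contour quantity for trend analysis, never absolute ml.

## Fiducial detection

Derivatives use a Savitzky–Golay smoothing differentiator (25 ms
window; order 3 for d¹/d², order 4 for d³) — raw finite differences are
unusable for third-derivative rules.  The dicrotic notch is the
earliest qualifying candidate in (peak + 20 ms, 60% of the beat]:
an explicit pressure minimum, a prominence-gated dp/dt maximum on the
falling limb, or a second-derivative minimum; if none exists the notch
is pinned at 1/3 of the beat and flagged.  Anacrotic shoulders are
third-derivative extrema gated on a genuine slope plateau (an interior
dp/dt extremum within 40 ms); A-type (pre-peak) takes precedence over
C-type (post-peak), and a second-derivative inflection is the fallback.
On noise-free analytic test beats these rules land within ~1 sample of
dense-grid oracles at 400 Hz.

## What the generator does and does not emulate

The simulator reproduces the *phenomenology* needed by the analysis:
realistic peripheral waveforms, correct signs and rough magnitudes of
the clinical aggregates under each deficit, age-dependent pulse
pressure, respiratory modulation, and deficit-specific morphology
changes (notch depression in hypovolemia, slow upstroke and prolonged
ejection in pump failure, notch effacement and high pulse pressure in
vasodilation).  It does not reproduce any proprietary simulator's exact
compartmentalization or numeric outputs: absolute feature values,
per-PC variance percentages and sensitivity magnitudes are
model-specific.  Conclusions drawn from passing tests are therefore
structural (directions, orderings, separability), not numeric
equivalences to any external tool.  Two known quantitative gaps, kept
deliberately rather than tuned away: the pooled normalized-waveform
family has a genuine third principal component (~5–9% variance;
dicrotic-notch depth and timing vary semi-independently across deficit
classes), and the three deficit classes, though cleanly separated in
the space of the leading principal components, place their
preload-vs-contractility contrast in the third component, so a
two-component silhouette understates the separation visible in
score plots.

## Problem sizes

Default runs used throughout the package and its tests: 15–30 s of
simulated time per scenario step (equilibrium is reached in ~5 beats
from the pressure-consistent initial state), ~45 steps across the three
60-year reduction arms, a four-age cohort of ~180 steps, and a 70 s
breathing run (~73 beats).  A full 60-year study executes in seconds on
one CPU core thanks to the JIT-compiled integrator.

## Known limitations

* No autonomic control loop: baroreflex action is modeled as explicit
  parameter overrides, not as a dynamic controller.
* Atria are passive (no atrial kick); coronary and cerebral branches
  are absent; gravity and posture are absent.
* The venous compartments are linear; venous collapse at strongly
  negative transmural pressure is not modeled, and deep hypovolemia
  ends in an explicit "unfillable" error rather than a collapse
  waveform.
* Artifact rejection and signal-quality indexing for real recordings
  are out of scope; the fiducial rules assume clean pressure data.
* Mechanical ventilation and extracorporeal support are not modeled.
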