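# Methods

## Scope and intent

`humansim` simulates the *untreated* evolution of a single adult trauma
casualty as a deterministic fixed-step state machine (default dt = 1 s,
horizon 14 400 s).  The design goal is triage-training realism at
multi-patient real-time speed, so every organ system is lumped to the
minimum that still produces clinically recognizable vital-sign
trajectories: one ventricle, one gas-exchange compartment per lung, one
intracranial compartment, and a scalar sympathetic drive coupling them.

## Patient generation

Sex is equiprobable and age uniform over 16–100 y — the population is
described only by ranges, so the least-informative distributions are used.
Heights are normal with sex-specific moments (178.4 ± 7.6 cm men,
164.7 ± 7.1 cm women); BMI is normal 23 ± 3 kg/m², truncated by rejection to
[15, 40] to exclude physiologically absurd extremes (the truncation bounds
are config-exposed; at ±2.7σ/+5.7σ they bias the mean by < 0.02 kg/m²).
Ideal body weight follows the sex-specific linear formula anchored at
152.4 cm, applied literally below the anchor with a 30 kg floor as a guard.
Blood volume (70 mL/kg) and dead space (2.2 mL/kg) scale with *ideal*
weight; resting VO₂ (3.5 mL/kg/min) scales with *actual* weight, so obese
patients run a higher metabolic load on normal-sized lungs.  Every
stochastic entry point takes an explicit seed (numpy Generator); the same
seed always reproduces the same patient.

## Anatomy

The body is a tree of 13 functional blocks rooted at the thorax (head,
neck, thorax, abdomen, pelvis, and left/right arm, forearm, thigh, leg).
Skin fractions follow the rule of nines (head 9 %, neck 1 %, trunk 36 %
split 18/9/9, arm segments 4.5 % each, leg segments 9 % each); resting
blood-flow fractions follow the textbook distribution of cardiac output
(brain 14 %, splanchnic+renal 40 %, …), both normalized to 1 exactly.
Blocks carry the vertebral segments passing through them; a cord lesion at
a level removes effectors by simple root anatomy: phrenic C3–C5 (complete
lesion at/above C3 → apnea), intercostals T1–T12, legs caudal to L2, and a
graded arm capacity equal to the share of brachial-plexus roots (C5–T1)
rostral to the lesion.  Partial lesions scale all capacities linearly;
boolean "intact" views threshold capacities at 0.5.

## Cardiovascular chain

Per step: EDV = 120 mL + four additive adjustments → ESV → SV = EDV − ESV
(clamped ≥ 0) → CO = SV·HR/1000 → MAP_th = CO·SVR (SVR fixed at 13) →
MAP_eff = min(MAP_th, VP) with CO_eff recomputed from the cap → DBP/SBP as
the fixed ratios 6/7 and 3/2 of MAP_eff.

The published description fixes only the bounds and signs of the four EDV
adjustments and gives ESV and the ventricular-pressure ceiling VP as
unprinted model-specific curves, so those are implemented as smooth
saturating surrogates:

* ΔEDV_volemia: −70·(1−r)^1.5 below normovolemia r = 1, +40·(1−e^(−2.5(r−1)))
  above; confined to [−70, +40] mL by construction.
* ΔEDV_pericardial: −110·(1−e^(−V/150 mL)); ΔEDV_pleural: −50·(1−e^(−P/10 mmHg));
  both ≤ 0, zero at zero insult.
* ΔEDV_sympathetic: +40·(1−e^(−3s)) ≥ 0.
* ESV = 50·(1 − 0.4 s) mL, so the resting stroke volume is 70 mL and full
  sympathetic drive raises ejection fraction.
* VP = 120·(1+0.3 s)·min(1,r)²·e^(−V_peri/200 mL) mmHg: an exsanguinated or
  compressed ventricle cannot generate pressure.  VP is what ultimately
  kills the hemorrhage and tamponade patients, because the +40 mL
  sympathetic venous-return bound can otherwise offset most of the −70 mL
  volemia bound.

Sympathetic drive is a soft-OR of three saturating stress terms —
hypotension below MAP 65 mmHg (scale 15), hypoxaemia below PaO₂ 60 (scale
15), hypercapnia above PaCO₂ 50 (scale 20) — filtered by a first-order lag
(τ = 30 s).  HR = 70 + s·(220 − age − 70).  The healthy closed loop settles
at MAP ≈ 65 mmHg with s < 0.01.  Note the deliberately low-normal MAP: the
resting chain (70 mL × 70 bpm × 13 mmHg·min/L) pins it, matching the
model's own arithmetic rather than a population norm.

## Respiratory chain

VA = RR·max(0, VT − dead space)·functional_fraction /1000.  Drive: RR = 14
+ 1.5/mmHg above PaCO₂ 42 + 0.5/mmHg below PaO₂ 60, capped at 35; VT = 7
mL/kg·IBW scaled by airway patency, multiplied by 0.6 when intercostals are
lost (diaphragm-only breathing), capped by any chest-wall ceiling, and zero
when the diaphragm is denervated.  While breathing, PaCO₂ relaxes (τ = 60 s)
to 0.863·RQ·VO₂/VA with RQ = 0.84, and PaO₂ to the alveolar gas equation
0.21·(760 − 47) − PaCO₂/RQ minus a fixed 5 mmHg A–a gradient (floor
5 mmHg).  The lags prevent step discontinuities when a pathology switches
ventilation instantly.

Apnea consumes a lumped whole-body O₂ store (calibrated at 27.7 mL/kg of
actual weight, the single knob fitted to the apneic death time; it stands
for FRC plus blood/tissue-bound oxygen).  PaO₂ falls proportionally to the
remaining store fraction relative to the start of the apneic interval, and
PaCO₂ rises at the textbook 3.5 mmHg/min.  SpO₂ always comes from the
Severinghaus (1979) closed form S = 100/(23400/(P³+150P)+1).  A complete
unilateral pneumothorax zeroes that lung's functional share (0.55 right /
0.45 left).

## Brain

CPP = MAP_eff − ICP exactly at every step; CBF sits at 0.7 L/min on the
autoregulation plateau (CPP 50–150 mmHg) and falls linearly to 0 below it.
ICP = 10·exp(V_bleed/50 mL) mmHg (exponential elastance).  GCS maps the
delivery proxy (CBF fraction × SpO₂/98) from 15 (proxy ≥ 0.9) linearly down
to 3 (proxy ≤ 0.2), capped at 8 above PaCO₂ 80 mmHg (CO₂ narcosis).  The
scale is a total score only.  Walking requires GCS ≥ 14, intact leg
innervation and no disabling lower-limb injury.

## Engine

Synchronous (Jacobi) update: pathology mutators write the new step's
accumulators, but every sub-model reads the *previous* step's accumulators
and cross-module values, so sub-model ordering inside a step is immaterial
and a preset's one-step footprint is exactly its accumulator set.  Every
run starts from a 600 s pre-insult settling run (≥ 5 gas lags) so T0 is the
model's own healthy equilibrium.  Death requires a fatal criterion
(CPP < 20 mmHg, SpO₂ < 40 %, CO_eff < 0.5 L/min) to hold for a 60 s dwell;
the reported time is the first entry into the dwell, at dt resolution.
Death times at dt = 1/0.5/0.25 s agree within 0.4 % across the reference
scenarios.  Twenty 4-hour patients simulate in ≈ 7 s on one CPU.

## Pathologies and calibration

Each preset mutates only its accumulators: hemorrhages drain blood at
rate·(MAP/70) mL/min (pressure-dependent, so bleeding decelerates in shock
and stops at zero pressure); tamponade fills the pericardium at a constant
rate; the airway burn closes the airway as e^(−t/τ); the chest burn decays
the tidal-volume ceiling toward 25 % of baseline; both burns leak plasma at
1 mL/min; the intracranial bleed grows at a constant rate that also leaves
the circulation; cord lesions install once at onset.

Each lethal preset has exactly one dominant free constant, fitted by
log-midpoint bisection until the simulated untreated death time matches its
reference value within 1 % (monotonicity of death time in the constant is
verified by sweep tests).  The apneic case is fitted first because its knob
(the O₂ store per kg) is config-level and shared.  Frozen values
(`src/humansim/data/calibration.yaml`): internal hemorrhage 63.17 mL/min at
MAP 70, tamponade 2.19 mL/min, airway-burn τ 6 635 s, chest-burn τ 3 669 s,
intracranial bleed 0.954 mL/min, O₂ store 27.73 mL/kg.  The venous forearm
hemorrhage (3 mL/min), simple pneumothorax (pleural pressure +2 mmHg) and
C5–C7 lesion are verified survivors, not fitted.  Calibration reproduces
outcome times; it does not claim the original model's internal
trajectories.

## What the generator does and does not emulate

The random-patient module emulates the demographic envelope of an adult
civilian casualty population (age, sex, stature, BMI and the derived
volumes).  It does not model comorbidities, medication, fitness, pregnancy
or pediatric physiology, and all patients share identical organ-level
parameters; passing tests therefore demonstrate internal consistency and
reproduction of the reference outcome times, not predictive validity for
real patients.

## Numerical choices and degenerate inputs

First-order lags use the exact discrete form 1−e^(−dt/τ), so halving dt
does not change equilibria.  SV, blood volume, O₂ store, CBF and PaO₂ are
floored (0 / 0 / 0 / 0 / 5 mmHg); GCS is clipped to [3, 15].  Zero SVR,
non-positive heights and negative volumes raise `ValueError`; any
non-finite state field raises `EngineFault` naming the field and time.
Bisection brackets are config-visible; an unbracketed calibration target
raises `CalibrationError` naming the preset.

## Known limitations

No treatment effects (the simulator models *untreated* evolution only), no
tension pneumothorax, no V/Q mismatch or shunt, constant SVR, no Cushing
response (intracranial hypertension does not raise MAP), no cardiac
arrhythmias, and a sympathetic surge that keeps MAP high in terminal
hypoxia where real patients would arrest.  GCS is a coarse oxygen-delivery
mapping, not a neurological exam.
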