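# humansim

A deterministic, real-time whole-body physiology simulator of **untreated
adult trauma casualties**, built for mass-casualty-incident training.  It
couples simplified heart, lung and brain models over a tree of anatomical
functional blocks, generates random patients, applies one of nine injury
presets (hemorrhages, tamponade, pneumothorax, burns, head trauma, cervical
cord lesions) and evolves twelve clinical and physiological parameters —
SpO₂, respiratory rate, heart rate, MAP, GCS, ability to walk, alveolar
volume, PaO₂, PaCO₂, blood volume, stroke volume, ICP — until death or a
4-hour horizon.  It is intended for developers of triage-training serious
games and for instructors who need plausible, reproducible vital-sign
trajectories for many patients at once, not for clinical prediction.

## The model

Patients are drawn from a simple adult population (age ~ U[16, 100], sex
equiprobable, height ~ N(178.4, 7.6) cm for men and N(164.7, 7.1) cm for
women, BMI ~ N(23, 3) truncated to [15, 40]).  Anthropometric baselines use
the Devine-type ideal body weight

    IBW = 50 kg (man) | 45.5 kg (woman) + 0.9 · (height − 152.4 cm)

with blood volume 70 mL/kg·IBW and dead space 2.2 mL/kg·IBW.

The cardiovascular chain each second is

    EDV  = 120 + ΔEDV_volemia + ΔEDV_pericardial + ΔEDV_pleural + ΔEDV_sympathetic   (mL)
    SV   = EDV − ESV(s)                     CO = SV · HR / 1000        (L/min)
    MAP_th = CO · SVR,  SVR = 13            MAP_eff = min(MAP_th, VP)
    DBP  = 6/7 · MAP_eff                    SBP = 3/2 · MAP_eff

where the four EDV adjustments are smooth saturating curves (volemia effect
bounded in [−70, +40] mL), VP is the left-ventricular pressure ceiling that
collapses with exsanguination or tamponade, and s ∈ [0, 1] is a lagged
sympathetic drive responding to hypotension, hypoxaemia and hypercapnia
(HR = 70 + s·(220 − age − 70)).

The lung uses VA = RR · (VT − dead space) · functional fraction, the
steady-state relation PaCO₂ = 0.863·VCO₂/VA (RQ = 0.84), the alveolar gas
equation for PaO₂, the Severinghaus dissociation curve for SpO₂, and a
finite whole-body O₂ store that is consumed during apnea.  The brain uses
CPP = MAP − ICP, an autoregulated CBF plateau of 0.7 L/min, a Marmarou-type
exponential ICP–volume curve for intracranial bleeding, and maps a brain
oxygen-delivery proxy to the GCS and the walking flag.

Death is declared when CPP < 20 mmHg, SpO₂ < 40 % or effective cardiac
output < 0.5 L/min persists for 60 s.  Each lethal preset has one dominant
rate constant calibrated by bisection against the reference untreated
times of death and frozen in `src/humansim/data/calibration.yaml`; see
`docs/methods.md` for the full account.

## Worked example

Simulate the atlanto-occipital-dislocation patient (a 61-year-old woman,
164 cm, 69 kg) untreated from t = 0:

```bash
humansim generate-patient --sex female --age 61 --height 164 --weight 69 --out p8.json
humansim simulate --patient p8.json --pathology spinal_C0 --out tl.csv --t0t4 t0t4.json
```

which logs `death at 348 s` and writes the five-point assessment table:

```
label   clock  spo2   rr    hr   map  gcs  walks  pao2  paco2  icp
   T0 0:00:00  97.3 15.2  70.5  64.9   15   True  93.8   42.8 10.0
   T1 0:01:27  95.2  0.0  70.5  64.9   15  False  76.6   47.7 10.0
   T2 0:02:54  89.8  0.0  77.5  81.3   15  False  58.2   53.0 10.0
   T3 0:04:21  76.1  0.0 128.8 143.8   13  False  40.9   57.9 10.0
   T4 0:05:48  38.6  0.0 151.6 153.0    6  False  22.5   63.2 10.0
```

Reading the rows: the complete C0 lesion stops the diaphragm at onset
(RR 0, walks False), the body oxygen store then drains — SpO₂ slides from
97 % to 39 % in under six minutes while PaCO₂ climbs at the apneic rate —
the sympathetic surge drives HR and MAP up, consciousness fades (GCS 15→6),
and the fatal SpO₂ dwell is entered at T4 = 348 s.

The nine-patient reference experiment (timelines, T0–T4 tables and a
summary of simulated vs expected outcomes) is regenerated with:

```bash
humansim run-validation --outdir validation_out
```

Other commands: `list-pathologies`, `calibrate`, `dump-curves`,
`dump-default-config` (every model constant in one YAML).

## Limitations

No treatments, no pediatric physiology, no toxicological or blast injuries;
vascular resistance is constant and V/Q mismatch is not modelled.  The
simulator is a training surrogate calibrated to reproduce outcome times,
not a validated patient-level predictor.
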