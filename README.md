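# oxiloop

An in-silico pulse oximeter and closed-loop oxygen titration simulator.

Hypoxaemic patients need supplemental oxygen held inside a target
saturation band — enough to relieve the deficiency, not so much that
oxygen toxicity becomes a risk. In practice that titration is done by
hand in intensive-care settings. `oxiloop` models the complete
computational chain of an automated alternative as testable software: a
two-wavelength photoplethysmography (PPG) front end, the streaming DSP
and vitals estimation of the reader side, the per-minute flow titration
logic of the delivery side, and a virtual patient that closes the loop —
so every stage can be exercised, measured and stressed without hardware
or patients. It is aimed at biomedical-engineering researchers and
students prototyping oximetry pipelines or oxygen-administration control
policies.

## The model

**Acquisition.** Red and Infra-red LEDs are time-multiplexed in the
four-slot cycle RED_ON, BOTH_OFF, IR_ON, BOTH_OFF and the photodiode is
sampled once per slot at 500 S/s, giving 125 S/s per optical channel plus
a 250 S/s dark-reference channel used for ambient subtraction.

**Vitals estimation.** Each channel is split into its non-pulsatile (DC)
and pulsatile (AC) parts by a fixed three-filter cascade (2nd-order
Butterworth low-pass at 0.1 Hz for DC tracking; 4th-order Butterworth
high-pass passing 0.5 Hz for DC removal; 11-tap Kaiser-window FIR
low-pass at 10 Hz for denoising), respecting the 0.5–4.0 Hz PPG band.
Every second the estimator computes

- the ratio of ratios `R = (AC_red/DC_red) / (AC_ir/DC_ir)`,
- `SpO2 = 110 − 25·R`, clamped to [0, 100] %,
- heart rate `HR = fs·60 / (samples per pulse)` from detected systolic
  peaks,
- perfusion index `PI = 100·AC_ir/DC_ir`,

and stabilizes SpO2 and HR with a 5-second weighted moving average.
Seconds without a detectable finger signal produce invalid records.

**Control.** The delivery side receives one record per second. Invalid
records stop oxygen immediately and display "Please Insert Your Finger";
valid records drive a fixed-step titration (default 0.5 L/min, at most
once per minute) toward the 94–98 % band, mapped affinely to the
proportional solenoid valve's drive voltage. A watchdog stops delivery
whenever no record has arrived for over a minute.

**Virtual patient.** True saturation relaxes first-order (τ = 45 s by
default) toward an equilibrium `min(100, baseline + gain·flow)`; the
reference hypoxaemic patient has baseline 85 % and gain 2 % per L/min.
The classical content/delivery relations `CaO2 = 1.34·Hb·SaO2 +
0.023·PaO2` and `DO2 = CO·CaO2` are included.

The PPG generator inverts the estimation model: given true SpO2, HR and
PI it emits the multiplexed detector stream that embeds exactly the
calibration ratio `R = (110 − SpO2)/25`, so ground truth is known for
every downstream stage.

## Worked example

Run the bundled 20-minute closed-loop session (reference hypoxaemic
patient, fixed-step titration):

```bash
oxiloop run examples/hypoxaemic_session.yaml --outdir session
```

```
steady-state true SpO2 96.15 % (sd 1.33) over final 300 s; final flow 5.5 L/min
logs in session
```

The controller ramps the flow from 0 by 0.5 L/min each minute until the
measured saturation enters the 94–98 % band, then holds near 5.5 L/min;
the patient's true saturation settles around 96 %, inside the band. The
directory contains `vitals.csv` (per-second SpO2/HR/PI records),
`commands.csv` (every valve command with its reason), `patient.csv`
(true-saturation trajectory and delivered flow), `display.csv` and
`summary.json`. `oxiloop plot session --out session.png` renders the
trajectories.

The open-loop pieces are also exposed:

```bash
oxiloop synth --spo2 92 --duration 20 --seed 3 --out demo
oxiloop estimate demo --out demo_vitals.csv
```

```
wrote 20 records (19 valid) to demo_vitals.csv
```

The first second is invalid (two heartbeats are needed before a rate
exists); afterwards the estimates track the generated truth closely,
e.g. record 1 reads SpO2 91.9 % for a true 92 %, HR 74.3 bpm for a true
75, PI 1.99 % for a true 2 %.

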