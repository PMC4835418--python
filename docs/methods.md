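# Methods

## Signal model

The generator works backwards from the quantities the estimator must
recover. Each optical channel is `DC + AC·w(φ(t))` plus ambient light and
optional white Gaussian noise, where `w` is a fixed zero-mean beat
waveform with unit peak-to-peak amplitude built from the first three
cardiac harmonics (relative amplitudes 1 : 0.5 : 0.2 with phase offsets
giving a fast systolic upstroke and slower diastolic decay). Three
harmonics keep the waveform band-limited: at the 4 Hz band ceiling the
highest component sits at 12 Hz, at typical heart rates well under the
10 Hz noise-filter cutoff. Because both channels share `w`, the shape
cancels from the ratio of ratios; only the amplitude allocation matters.
The Infra-red contrast is pinned by the perfusion index
(`AC_ir = PI/100 · DC_ir`) and the Red contrast is solved from the
calibration target, `AC_red = R · PI/100 · DC_red` with
`R = (110 − SpO2)/25`. This makes the calibration exactly invertible and
gives every downstream stage a known ground truth. Dark slots carry
ambient light only. The generator is deliberately not an optics model:
no Beer–Lambert absorption, LED spectra or detector electronics — so
passing tests demonstrate correctness of the signal chain, not clinical
accuracy of the calibration line, which in a real device must come from
clinical measurements.

Artifacts are typed overlays: no-finger dropouts (pulsatile component
zeroed, DC collapsed to ambient, truth flagged invalid), mains-like
interference tones, and linear baseline drifts.

## Filters

The three designs are fixed: DC tracking (2nd-order Butterworth
low-pass, 0.1 Hz), DC removal (4th-order Butterworth high-pass) and
noise removal (10th-order, i.e. 11-tap, FIR with Kaiser window β = 0.5,
cutoff 10 Hz), all at the 125 S/s channel rate. Two interpretation
choices were open:

- The high-pass is stated with stop edge 0.1 Hz and pass edge 0.5 Hz but
  no half-power point; it is realized with −3 dB at the 0.5 Hz pass
  edge, which attenuates 0.1 Hz by ≈56 dB and so satisfies the stop
  intent. Whether the original design placed the half-power point at the
  pass edge is unknown; this is the conservative reading.
- "10th order" FIR is read as 11 taps.

Consequences worth knowing: an 11-tap FIR at 125 S/s has a transition
band of roughly 11 Hz, so it already attenuates inside the cardiac band
(gain ≈0.95 at 2.5 Hz, ≈0.88 at 4 Hz), and the high-pass is at half
power exactly at the 0.5 Hz band edge. Tones in the 1–3 Hz interior pass
the AC path with gain ≥0.9; the extreme band edges see 0.7–0.88. This
droop cancels exactly in the ratio of ratios (both channels are filtered
identically), so SpO2 recovery is unaffected; it biases the perfusion
index low by about 5–17 % of its value depending on heart rate (≈1.78 %
measured for a true 2 % profile at 75 bpm). A production device would
either calibrate this out or use a longer FIR; here the specified
designs are kept and the bias is documented and tested.

Filters run as streaming, stateful operators; chunked application is
bit-identical to one-shot application (the FIR is applied as an explicit
tapped-delay-line convolution so chunk boundaries cannot reorder the
per-sample dot products). Both IIR filters are primed to steady state
for the first observed sample — the DC tracker outputs it, the high-pass
nulls it — because a cold start at 0.1 Hz injects a step transient that
takes tens of seconds to decay and would dwarf the millivolt-scale
pulsatile signal. The warm-up counter reported with extracted components
is the AC path's settling estimate (slowest-pole decay to 1e-3, ≈5.7 s
at 125 S/s).

## Estimation

The per-second tick appends one second of filtered samples to an 8 s
sliding analysis window (≥4 beats at the 30 bpm floor, ≥2 beats within
2 s at typical rates). Systolic peaks are detected with a 0.25 s
refractory interval (the 4 Hz band ceiling) and a prominence floor of a
quarter of the window's peak-to-peak span. AC amplitude is the mean
peak-to-peak across complete inter-beat intervals; DC is the window mean
of the tracker output. Heart rate applies the samples-per-pulse formula
to the span between the first and last detected peak and the number of
complete intervals — the same average the formula describes, measured
without partial-beat truncation error. SpO2 and HR are smoothed by a
5-second weighted moving average with linearly increasing weights
(1…5); the choice to smooth after, not before, the calibration mapping
is arbitrary for a linear map at these fluctuation scales and was fixed
as "after". The perfusion index is reported unsmoothed.

A second is marked finger-absent when the raw (ambient-corrected)
Infra-red mean falls below 5 % of the nominal detector level or the
last-second AC contrast falls below 0.1 % — the raw mean rather than the
tracker output, which lags a probe removal by many seconds. On absence
the signal path (filters and window) is restarted, since state carried
across a removal would contaminate several seconds after reinsertion
with a DC-step transient. Two consequences are accepted and tested: the
first record after a session start or reinsertion is invalid until two
beats have been observed (real oximeters likewise blank their display
for a few seconds), and validity transitions may lag an artifact edge by
up to one second.

## Control and patient

The titration law is intentionally minimal: ±0.5 L/min (configurable)
at most once per minute, driven by the smoothed SpO2, clipped to
[0, 15] L/min, targeting 94–98 %. Invalid records stop flow immediately
and are exempt from the once-per-minute cadence; after any stop the flow
restarts from zero rather than restoring its prior value (conservative
safe state). Flow maps to valve voltage as `V = 10 · flow/15`. The
watchdog fires once per stall episode when staleness strictly exceeds
60 s and also resets the reader pipeline. Illness-specific bands (e.g.
88–92 % for CO2 retainers) and guideline prescription tables are out of
scope; the band and step are configuration.

The virtual patient is a first-order lag: equilibrium
`min(100, baseline + gain·flow)`, exact-exponential update per step (so
the noise-free trajectory is independent of step size), optional
per-update Gaussian jitter, clamped to [0, 100]. The reference patient —
baseline 85 %, gain 2 %/(L/min), τ = 45 s, jitter 0.3 % — was chosen as
a plausibly severe but oxygen-responsive case: it needs 4.5–6.5 L/min to
sit in the target band, so a session exercises a long up-titration ramp.
This model has no gas-exchange physiology, no dissociation-curve shape,
no CO2 dynamics; it exists to close the loop with a monotone, lagged
dose-response, which is all the fixed-step controller assumes.

## Session composition and sizes

The closed loop ticks at 1 s: synthesize the second at the patient's
current true saturation (cardiac phase and noise streams continue across
seconds), demultiplex, ambient-correct, estimate, offer the record to
the transport (default lossless, zero latency; drop probability and
latency are opt-in), deliver to the controller, check the watchdog, then
advance the patient one second under the commanded flow. All child seeds
derive from the single session seed, so a (config, seed) pair determines
every log byte; CSV floats are written with `%.17g` and parsed in
round-trip mode so write→read is exact.

The standard experiment is a 20-minute session (1200 s, 600 000 raw
samples) summarized over its final 5 minutes — long enough for the
~9-minute titration ramp plus several time constants of settling, and it
runs in about a second. Test simulations use 10–20 s streams, which
cover warm-up plus a stable analysis window at every grid heart rate.

## Known limitations

- The calibration line `SpO2 = 110 − 25R` is used as given; no clinical
  calibration is modelled, and the generator embeds the same line, so
  closed-loop accuracy statements are about the pipeline, not about
  oximetry physics.
- Perfusion index carries the documented filter-droop bias.
- Motion artifacts are injected but no motion-robust estimation is
  implemented; heavy motion simply degrades or invalidates records.
- The transport abstracts a wireless link as drop probability plus fixed
  latency; no pairing, reordering or duplication.
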