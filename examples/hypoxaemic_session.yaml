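# 20-minute closed-loop titration of the reference hypoxaemic patient
duration_s: 1200
seed: 1
profile:
  heart_rate: 75
  perfusion_index: 2.0
  noise_sd: 0.002
patient:
  baseline_spo2: 85
  gain: 2.0
  tau: 45
  noise_sd: 0.3
controller:
  step: 0.5
  max_flow: 15
  band: [94, 98]
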