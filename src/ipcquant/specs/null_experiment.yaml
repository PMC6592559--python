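# All-null experiment: every treatment class has zero latent response, so
# any structure the pipeline reports is noise.  Used for calibration checks.
seed: 7
n_brains: 5
neurons_per_brain: 2
frame_rate: 0.2
duration: 1000.0
application_time: 100.0
baseline_cfp: 1000.0
baseline_yfp: 1500.0
baseline_gfp: 800.0
gain: 0.5
spillover: 0.357
background: 50.0
background_drift: 0.0
noise_sd: 1.5
bleach_tau: null
neuron_cv: 0.15
treatments:
  HL3:
    role: negative_control
    kinetics: {a_slow: 0.0, a_fast: 0.0}
  mockA:
    role: experimental
    kinetics: {a_slow: 0.0, a_fast: 0.0}
  mockB:
    role: experimental
    kinetics: {a_slow: 0.0, a_fast: 0.0}
  mockC:
    role: experimental
    kinetics: {a_slow: 0.0, a_fast: 0.0}
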