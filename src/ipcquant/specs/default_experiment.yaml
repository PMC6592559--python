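# Demonstration experiment: bath-application pharmacology panel on IPCs
# expressing the Epac1-camps cAMP sensor.  Latent amplitudes are set so the
# noiseless iFRET peaks land near the approximate percent changes the
# treatment classes are meant to illustrate (slow ~10% single peptides,
# ~15% + fast ~8% transient for the co-application, post-400 s decline for
# the half dose, fast component blocked under TTX).  Kinetic time constants
# are phenomenological, not measured values.
seed: 2019
n_brains: 5
neurons_per_brain: 4
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
  NKH477:
    role: positive_control
    kinetics: {a_slow: 0.26, tau_slow: 100.0}
  PDF:
    role: experimental
    kinetics: {a_slow: 0.095, tau_slow: 250.0}
  PDF+TTX:
    role: experimental
    kinetics: {a_slow: 0.095, tau_slow: 250.0}
  sNPF:
    role: experimental
    kinetics: {a_slow: 0.095, tau_slow: 250.0}
  sNPF+TTX:
    role: experimental
    kinetics: {a_slow: 0.095, tau_slow: 250.0}
  sNPF+PDF:
    role: experimental
    kinetics: {a_slow: 0.14, tau_slow: 200.0, a_fast: 0.077,
               tau_fast_rise: 10.0, tau_fast_decay: 40.0}
  sNPF1/2+PDF1/2:
    role: experimental
    kinetics: {a_slow: 0.095, tau_slow: 200.0, a_fast: 0.04,
               tau_fast_rise: 10.0, tau_fast_decay: 40.0,
               t_decline: 400.0, tau_decline: 600.0}
  sNPF+PDF+TTX:
    role: experimental
    kinetics: {a_slow: 0.122, tau_slow: 200.0, a_fast: 0.077,
               tau_fast_rise: 10.0, tau_fast_decay: 40.0,
               ttx_blocks_fast: true}
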