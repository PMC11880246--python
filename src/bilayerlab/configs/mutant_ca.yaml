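# D91/93/94A mutant channel in the pure CaCl2 bath (150:15 mM).
# Ground truth: 33.75 pS; E_rev from the bath (~29.90 mV); Po ~ 0.3.
mode: simulate
voltages_mV: [-60.0, -25.0, 75.0, 90.0, 105.0]
duration_s: 60.0
channel:
  conductance_pS: 33.75
  k_open_per_s: 21.43
  k_close_per_s: 50.0
  noise_sd_pA: 0.8
  filter_cutoff_Hz: 1000.0
  sampling_rate_Hz: 10000.0
bath:
  cis: {CaCl2: 150}
  trans: {CaCl2: 15}
  permeabilities: {Ca2+: 1.0}
  rt_over_f_mV: 25.97
seed: 3
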