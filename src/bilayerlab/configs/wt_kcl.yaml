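# WT channel in the asymmetric KCl bath (500 mM cis : 50 mM trans).
# Simulator ground truth: 27.37 pS, E_rev = +52.77 mV; Po ~ 0.3.
# Voltages bracket E_rev over a 200 mV span while keeping the unitary
# amplitude well above the filtered noise floor.
mode: simulate
voltages_mV: [-50.0, -10.0, 110.0, 130.0, 150.0]
duration_s: 60.0
channel:
  conductance_pS: 27.37
  e_rev_mV: 52.77
  k_open_per_s: 21.43
  k_close_per_s: 50.0
  noise_sd_pA: 0.8
  filter_cutoff_Hz: 1000.0
  sampling_rate_Hz: 10000.0
bath:
  cis: {KCl: 500}
  trans: {KCl: 50}
  permeabilities: {K+: 1.0}
  rt_over_f_mV: 25.97
  invert: monovalent
  reference_cation: K+
  target_anion: Cl-
seed: 1
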