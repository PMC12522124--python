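# Kinetic simulation / fit configuration (units as named in the keys).
geometry:
  R_nm: 44.0
  d_nm: 4.0
  lipid_mg_per_ml: 20.0
  lipid_density_g_per_ml: 1.0

polymer:
  name: P(C5EG6)12k
  m: 5
  n: 6
  mw_kg_mol: 12.0
  lcst_C: 35.0

c_polymer_wt_percent: 1.0

params:            # used by `simulate` and `translocation-time`
  k_a: 0.05        # 1/s
  k_d: 5.0e-4      # 1/s
  c_sat: 0.01      # mass fraction of the membrane

sequence:
  Delta_ms: 100.0
  delta_ms: 2.0

noise_sigma: 0.02  # fallback per-point noise for traces without an error column

# prior:           # optional override of the log-uniform prior bounds
#   k_a: [1.0e-4, 1.0e+2]
#   k_d: [1.0e-7, 1.0e-1]
#   c_sat: [1.0e-5, 1.0]
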