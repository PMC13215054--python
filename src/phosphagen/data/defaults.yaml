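# Default model configuration.
#
# `constants` and `initial` carry the published resting pools and
# physical constants of the model (squid-axon concentrations, kinase
# equilibrium constants, free-energy constants).
#
# `terminal` is a SYNTHETIC parameter set: the per-terminal per-AP costs,
# decay constants, base rate and volume of the study's terminals are not
# published with the model and these placeholders only match them in
# order of magnitude.  Replace this block with real values if you have
# them.
constants:
  k_ad: 1.0          # adenylate kinase equilibrium constant
  k_ph: 39.6         # arginine kinase equilibrium constant
  delta_g0: -30.6    # kJ/mol, standard free energy of ATP hydrolysis
  gas_constant: 8.31445e-3   # kJ/mol/K
  temperature: 300.0 # K
initial:
  atp0: 2.16         # mM
  argp0: 7.5         # mM
  arg0: 3.3          # mM
  pi0: 3.8           # mM (low end of the measured 3.8-17.8 mM range)
terminal:
  name: synthetic-default
  synthetic: true
  n_atp:             # ATP molecules per action potential (SYNTHETIC)
    Na: 4.0e5
    Ca: 1.0e5
    NT1: 1.0e5
    NT2: 5.0e4
    NT3: 2.0e4
  tau:               # decay constants, s (SYNTHETIC)
    Na: 5.0
    Ca: 0.5
    NT1: 0.1
    NT2: 1.0
    NT3: 10.0
  base_rate: 0.05    # mM/s, non-signalling consumption (SYNTHETIC)
  volume: 300.0      # um^3 (SYNTHETIC)
  mito_density: 6.3  # %, near the published type-Ib densities
  max_rate_per_density: 0.154  # mM/s per 1% density (adult-thorax cap;
                               # the larval-brain cap is 0.079)
  phosphagen_present: true
protocol:
  preset: locomotion # locomotion | ca_pumping | train_60hz | train_80hz
production:
  turnover: hill_inverse
  k_half: 0.5        # 1/mM, inverse-ES at half-maximal turnover
  h: 2.0             # Hill coefficient
  cap_exponent: 5.0
equilibration:
  tol: 1.0e-10
  max_iter: 100
simulation:
  dt: 1.0e-4         # s
  record_stride: 10
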