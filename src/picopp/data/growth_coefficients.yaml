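# Temperature-growth coefficients for the three picophytoplankton groups.
# version 1 -- edit a copy and pass it to load_growth_params() to override.
version: 1
constants:
  boltzmann_k_ev_per_k: 8.62e-5
  celsius_to_kelvin_offset: 273.15
prochlorococcus:
  # concave-down quadratics in temperature (degC), mu in 1/day
  eMIT9312: {a0: -4.17, a1: 0.40, a2: -0.0086}
  eMED4: {a0: -1.11, a1: 0.14, a2: -0.0035}
synechococcus:
  # ln mu = -E/(k T) + intercept, T in kelvin, E in eV
  activation_energy_ev: 0.73
  ci_activation_energy_ev: [0.60, 0.88]
  intercept_ln_mu: 28.13
  ci_intercept_ln_mu: [23.20, 34.15]
  fitted_range_c: [10.0, 34.0]
picoeukaryotes:
  activation_energy_ev: 0.86
  ci_activation_energy_ev: [0.68, 1.07]
  intercept_ln_mu: 33.85
  ci_intercept_ln_mu: [26.94, 42.35]
  # below this total chlorophyll the temperature relationship is not
  # significant and the model tends to overestimate growth
  low_chl_threshold_mg_m3: 0.5
  low_chl_overestimate_factor: 1.58
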