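# Default run configuration: growth/angiogenesis constants, solver
# resolution, the virtual-cohort kinetics grid and the therapy operators.
# Units: D, rho and the motilities in mm^2/yr and 1/yr; all other rates
# in 1/day; lengths in mm; doses in Gy.

model:
  D: 305.0            # aggressive-preset net invasion rate, mm^2/yr
  rho: 83.0           # aggressive-preset net proliferation rate, 1/yr
  K: 2.39e5           # carrying capacity, cells/mm^3
  D_h: null           # hypoxic motility; null -> same as D
  D_v: null           # vessel motility; null -> 0.1 * D
  D_a: 3139.0         # angiogenic-factor diffusivity, mm^2/yr
  hypoxia_rate: 0.02
  reoxygenation_rate: 0.1
  necrosis_rate: 0.05
  vascular_sufficiency_threshold: 0.05
  vascular_sufficiency_width: 0.005
  necrosis_threshold: 0.03
  vessel_growth_rate: 0.1
  a_halfsat: 1.0
  a_production_h: 40.0
  a_production_c: 0.4
  a_decay: 2.0
  a_uptake_vessel: 1.0
  a_consumption_growth: 10.0
  vessel_destabilization_rate: 0.12
  a_destabilization_halfsat: 3.0
  vascular_fraction_normal: 0.05

solver:
  dr: 0.25            # radial step, mm
  r_max: 100.0        # domain extent, mm
  rtol: 1.0e-5
  atol_density: 1.0
  atol_a: 1.0e-6
  event_tol: 0.1      # radius-crossing acceptance, mm
  max_horizon: 15000.0

cohort:
  rho_bounds: [8.3, 83.0]
  n_rho: 11
  D_bounds: [1.43, 143.0]
  n_D: 13
  start_sizes_cm: [1.5, 2.5, 3.5]

therapy:
  aa:
    angiogenic_action_factor: 100.0
    h_to_c_multiplier: 2.0
    c_to_h_multiplier: 0.5
    duration_days: 42.0
  radiotherapy:
    # linear map rho -> alpha spanning the patient-specific radiosensitivity
    # range reported for glioblastoma over this cohort's rho axis
    alpha_slope: 0.003     # Gy^-1 per yr^-1
    alpha_intercept: 0.025 # Gy^-1
    dose_per_fraction: 2.0
    n_fractions: 30
    alpha_beta_ratio: 10.0
    oer_max: 3.0

imaging:
  t1gd_fraction: 0.80
  t2_fraction: 0.16
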