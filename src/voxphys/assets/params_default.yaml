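# Default physical parameters for the muscle-controlled triangular body-cover
# voice synthesizer (female-scaled larynx).
#
# None of these constants are fitted to any evaluation outcome; they are
# lineage defaults (Kelvin-type laryngeal muscle models, body-cover rules,
# wave-reflection tract constants) chosen once so that the synthesizer
# phonates with physiologic fundamental frequency and airflow across the
# sampled control grid.  All values are SI unless noted.
version: 1

tissues:
  # Modified Kelvin (standard-linear-solid) fibrous tissue entries.
  #   passive stress: sigma_p(eps) = sigma0 * (exp(B*eps) - 1)   [Pa]
  #   active  stress: a * sigma_am * max(0, 1 - b_act*(eps - eps_m)^2)
  #   dynamics:       tau_s * ds/dt + s = sigma_qs(eps, a) + tau_e * d(sigma_p)/dt
  CT:  {L0: 13.8e-3, area: 40.0e-6, sigma_am: 87.0e3,  eps_m: 0.0,  b_act: 1.5, sigma0: 2.2e3, B: 7.0, tau_s: 0.04, tau_e: 0.01}
  TA:  {L0: 10.0e-3, area: 40.0e-6, sigma_am: 105.0e3, eps_m: 0.2,  b_act: 1.5, sigma0: 1.0e3, B: 6.5, tau_s: 0.04, tau_e: 0.01}
  LCA: {L0: 14.0e-3, area: 11.0e-6, sigma_am: 100.0e3, eps_m: 0.4,  b_act: 1.5, sigma0: 1.5e3, B: 6.0, tau_s: 0.04, tau_e: 0.01}
  IA:  {L0: 9.0e-3,  area: 12.0e-6, sigma_am: 100.0e3, eps_m: 0.4,  b_act: 1.5, sigma0: 1.5e3, B: 6.0, tau_s: 0.04, tau_e: 0.01}
  PCA: {L0: 15.0e-3, area: 25.0e-6, sigma_am: 100.0e3, eps_m: 0.4,  b_act: 1.5, sigma0: 1.5e3, B: 6.0, tau_s: 0.04, tau_e: 0.01}
  LIG: {L0: 10.0e-3, area: 6.0e-6,  sigma_am: 0.0,     eps_m: 0.0,  b_act: 0.0, sigma0: 1.2e3, B: 8.5, tau_s: 0.04, tau_e: 0.01}
  MUC: {L0: 10.0e-3, area: 5.0e-6,  sigma_am: 0.0,     eps_m: 0.0,  b_act: 0.0, sigma0: 0.8e3, B: 6.0, tau_s: 0.04, tau_e: 0.01}

posture:
  # Scalar cricothyroid-rotation force balance: lever gain on CT tension,
  # kinematic CT shortening per unit fold strain, and an effective gain on
  # active TA shortening (TA acts mostly on the body; only part of its
  # active tension shortens the fold).
  g_ct: 0.35          # CT lever/mechanical-advantage gain (dimensionless)
  kappa_ct: 0.72      # eps_CT = -kappa_ct * eps (fold strain -> CT strain)
  g_ta_active: 0.10   # fraction of active TA stress entering the length balance
  strain_min: -0.30   # physiologic strain band
  strain_max: 0.60
  # Adduction rules (triangular prephonatory glottis).
  xi02_max: 1.5e-3    # half-width at the vocal processes at full abduction [m]
  k_pca: 0.25         # abductor weight of PCA in the effective adduction level
  cartilaginous_length: 3.0e-3  # posterior cartilaginous glottis length [m]
  pgo_gain: 0.7       # posterior-gap area = gain * cart_length * max(xi02, 0)

body_cover:
  # Female-scaled reference geometry at zero strain and the empirical rules'
  # material constants.
  L0: 10.0e-3         # membranous fold length [m]
  T0: 3.0e-3          # fold (vertical) thickness [m]
  Dc0: 1.0e-3         # cover depth [m]
  Db0: 3.0e-3         # body depth [m]
  rho_tissue: 1040.0  # [kg/m^3]
  nodal: 0.7          # lower-mass fraction of the cover thickness
  mu_cover: 800.0     # cover shear modulus [Pa]
  mu_body: 1200.0     # body shear modulus [Pa]
  c_kc: 0.35          # cover-cover coupling spring, fraction of sqrt(ku*kl)
  zeta_u: 0.1         # damping ratios
  zeta_l: 0.1
  zeta_b: 0.15
  zeta_col: 0.4       # added damping ratio during collision
  eta_nl: 1.0e6       # cubic spring coefficient [1/m^2]
  k_col_factor: 3.0   # collision spring = factor * mass spring, per unit length
  x_l0_offset: 1.5e-4 # prephonatory convergent offset of the lower mass [m]
  x_u0_offset: 0.0    # upper-mass prephonatory offset [m]
  thickness_rule: 0.8 # T = T0 / (1 + rule*eps)

flow:
  k_trans: 1.0        # lumped transglottal kinetic loss coefficient
  rho_air: 1.14       # warm humid air [kg/m^3]
  c_air: 350.0        # speed of sound [m/s]

tract:
  attenuation: 0.996      # per-section propagation factor at 44.1 kHz
  lung_reflection: -0.8   # absorbing lung-end reflection (pressure-release sign,
                          # magnitude 0.8; the lungs approximate a soft termination)
  supraglottal_female: area_female_ae.csv
  supraglottal_female_a: area_female_aa.csv
  supraglottal_male: area_male_ae.csv
  supraglottal_male_a: area_male_aa.csv
  subglottal: area_subglottal.csv

simulation:
  fs: 44100.0
  duration: 0.8       # [s]
  onset_ramp: 0.05    # lung-pressure ramp [s]
  feature_window: 0.05  # analysis window at the end of the run [s]

conditioning:
  lp_cutoff: 1100.0   # Chebyshev-II low-pass edge [Hz]
  lp_order: 10
  lp_stop_atten: 60.0 # stopband attenuation [dB] (ripple spec not printed; choice)
  target_fs: 8192.0
  hp_cutoff: 60.0     # Butterworth high-pass [Hz]
  hp_order: 4
  iop_lp_cutoff: 80.0
  iop_lp_order: 5
  iop_target_fs: 256.0

features:
  oq_threshold: 0.10  # open-phase amplitude threshold (fraction of peak-to-peak)
  h1h2_search_hz: 20.0

corrections:
  spl_db: -28.5       # lip output -> 10 cm microphone distance [dB]
  ps_cmh2o: -3.37     # clinical-vs-synthetic mean offset [cm H2O]

grid:
  # Sustained-phonation control lattice for Monte Carlo sampling.
  a_CT:  {lo: 0.0, hi: 1.0, step: 0.1}
  a_TA:  {lo: 0.0, hi: 1.0, step: 0.1}
  a_LCA: {lo: 0.2, hi: 0.8, step: 0.1}
  a_PCA: {lo: 0.0, hi: 0.1, step: 0.1}
  a_IA:  {lo: 0.2, hi: 0.8, step: 0.1}
  P_L:   {lo: 500.0, hi: 2000.0, step: 150.0}

regression:
  dropout: 0.10
  learning_rate: 1.0e-3
  epochs: 100
  batch_size: 64

ibif:
  # Nominal adult neck/trachea parameters for the accelerometer inverse filter.
  skin_mass: 2.0      # [kg/m^2]
  skin_stiffness: 1.3e6   # [N/m^3]
  skin_damping: 600.0 # [N s/m^3]
  trachea_length: 0.115   # [m]
  sensor_depth: 0.05  # sensor position below the glottis [m]
  sensitivity: 1.0    # accelerometer sensitivity [V/(m/s^2)]
  trachea_area: 2.5e-4    # [m^2]
  bounds_rel: 0.5     # default calibration bounds: +/-50% around nominal
  tikhonov: 1.0e-4    # inversion floor, relative to max |H|
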