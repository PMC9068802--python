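fit:
  n_restarts: 2
models:
- 1a
- 1b
simulate:
  birth_year_range:
  - 1986
  - 1999
  means:
    delayed:
      b_male_x: 0.6
      b_male_y: 0.06
      b_mod_y: 0.0
      b_yob_x: 0.05
      b_yob_y: 0.005
      mu_x: 1.79
      mu_y: 2.94
    immediate:
      b_male_x: 0.6
      b_male_y: 0.06
      b_mod_y: 0.0
      b_yob_x: 0.05
      b_yob_y: 0.005
      mu_x: -1.33
      mu_y: 2.61
    missing:
      b_male_x: 0.6
      b_male_y: 0.06
      b_mod_y: 0.0
      b_yob_x: 0.05
      b_yob_y: 0.005
      mu_x: -0.7
      mu_y: 2.67
  missing_rates:
    attainment: 0.35
    performance: 0.0
  n_dz: 180
  n_mz: 220
  p_delayed: 0.26
  p_discordant_dz: 0.13
  p_discordant_mz: 0.04
  p_male: 0.46
  p_status_missing: 0.33
  paths:
    delayed:
      a_xx: 5.4
      a_yx: 0.53
      a_yy: 0.64
      ap_yx: 0.0
      ap_yy: 0.0
      c_xx: 0.98
      c_yx: 0.04
      c_yy: -0.13
      cp_yx: 0.0
      cp_yy: 0.0
      e_xx: 3.25
      e_yx: 0.19
      e_yy: 0.43
      ep_yx: 0.0
      ep_yy: 0.0
    immediate:
      a_xx: 7.11
      a_yx: 0.66
      a_yy: 0.53
      ap_yx: 0.0
      ap_yy: 0.0
      c_xx: 3.64
      c_yx: 0.57
      c_yy: -0.16
      cp_yx: 0.0
      cp_yy: 0.0
      e_xx: 3.81
      e_yx: 0.22
      e_yy: 0.44
      ep_yx: 0.0
      ep_yy: 0.0
    missing:
      a_xx: 7.08
      a_yx: 0.65
      a_yy: 0.56
      ap_yx: 0.0
      ap_yy: 0.0
      c_xx: 2.74
      c_yx: 0.53
      c_yy: 0.0
      cp_yx: 0.0
      cp_yy: 0.0
      e_xx: 3.69
      e_yx: 0.2
      e_yy: 0.45
      ep_yx: 0.0
      ep_yy: 0.0
  performance_offset: 538.0
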