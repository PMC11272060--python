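# Steady-state operating conditions, feed rates and overall stoichiometric
# yields of the two oxic/anoxic cycling enrichment reactors (low-frequency
# R4: 4 cycles/day; high-frequency R32: 32 cycles/day).  Values as printed
# in the study's summary table; sds are linear-propagation standard
# deviations.  This file lets the reproduce mode run without raw data.
operation:
  volume_L: 0.75
  hrt_h: 48.0
  srt_h: 48.0
  temperature_K: 293.15
  pressure_atm: 1.0
  gas_flow_L_h: 24.0
  steady_state_days: 76.0
feeds_c_mmol_h:
  acetate: {value: 0.94, sd: 0.08}
  propionate: {value: 1.00, sd: 0.09}
  butyrate: {value: 0.75, sd: 0.07}
feed_no3_n_mmol_h: {value: 0.93, sd: 0.04}
reactors:
  R4:
    schedule:
      cycles_per_day: 4
      t_oxic_h: 4.0
      t_anoxic_h: 2.0
      net_oxic_h: 16.0
      net_anoxic_h: 8.0
    yields:
      y_n2o_no3: {value: 0.07, sd: 0.04}
      y_x_s: {value: 0.44, sd: 0.04}
      y_no3_s: {value: 0.30, sd: 0.04}
      y_o2_s: {value: 0.29, sd: 0.03}
      y_co2_s: {value: 0.53, sd: 0.03}
    phase_n2o_n_mmol_h:
      aerobic: {value: 0.057, sd: 0.037}
      anaerobic: {value: 0.037, sd: 0.039}
  R32:
    schedule:
      cycles_per_day: 32
      t_oxic_h: 0.5
      t_anoxic_h: 0.25
      net_oxic_h: 17.0
      net_anoxic_h: 7.0
    yields:
      y_n2o_no3: {value: 0.07, sd: 0.04}
      y_x_s: {value: 0.46, sd: 0.06}
      y_no3_s: {value: 0.20, sd: 0.01}
      y_o2_s: {value: 0.40, sd: 0.05}
      y_co2_s: {value: 0.51, sd: 0.05}
    phase_n2o_n_mmol_h:
      aerobic: {value: 0.042, sd: 0.029}
      anaerobic: {value: 0.038, sd: 0.019}
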