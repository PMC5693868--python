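analysis:
  amplitude_threshold_frac: 0.25
  background_radius: null
  dt_s: 12.0
  initial_window: 3
  min_prominence: 0.1
  smooth_window: 3
domains:
  central_mesoderm: 25.8
  lateral_mesoderm: 38.6
  mesectoderm: 47.2
forces: {}
genotype: wildtype
geometry:
  apical_sections: 3
  basal_sections: 3
  inner_radius: 13.0
  lateral_sections: 5
  n_cells: 84
  vitelline_radius: 20.0
log_level: INFO
output_dir: results
seed: 0
solver:
  contact_tol: 1.0e-08
  drag: 0.05
  dt: 0.01
  force_scale: 10.0
  incompressibility_tol: 1.0e-06
  max_constraint_iters: 80
  mu: 1.0
  output_interval: 1.0
  pressure_cap_frac: 0.1
  pressure_gain: 2.0
  pressure_p0: 0.4
  yolk_area_cap_frac: 0.06
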