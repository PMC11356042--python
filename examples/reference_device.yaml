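coil:
  outer_radius_um: 2000.0
  n_turns: 97
  wire_width_um: 10.0
  wire_height_um: 10.0
  wire_spacing_um: 10.0
  current_ma: 400.0
  conductivity_s_per_m: 59600000.0
channel:
  width_um: 50.0
  height_um: 50.0
  length_um: 4800.0
  coil_separation_um: 30.0
  lateral_offset_um: 0.0
fluid:
  density_kg_per_m3: 1000.0
  viscosity_pa_s: 0.001
  flow_rate_ul_per_min: 1.0
  relative_permeability: 1.0
  relative_permittivity: 80.0
particle:
  diameter_nm: 50.0
  relative_permeability: 5000.0
  relative_permittivity: 10.0
  mass_density_kg_per_m3: 5200.0
electrodes:
  height_um: 50.0
  length_um: 500.0
  voltage_v: 5.0
  conductivity_s_per_m: 59600000.0
stack:
  wall_thickness_um: 5.0
  pdms_relative_permittivity: 2.7
simulation:
  horizon_s: 60.0
  injection_window_s: 10.0
  n_particles: 500
  seed: 0
  rtol: 1.0e-05
  atol_m: 1.0e-08
  packing_fraction: 0.01
  occupancy_model: parallel-column
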