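# Default ring-trap experiment: every value spelled out explicitly.
# Loading an empty config yields exactly this configuration.
geometry:
  ring_inner_radius_um: 20.0      # 40 um internal diameter
  ring_outer_radius_um: 40.0      # electrode width 20 um
  counter_inner_radius_um: 60.0   # 20 um gap to the grounded plane
  domain_radius_um: 125.0         # half the channel width
  channel_height_um: 40.0
  channel_width_um: 250.0
  channel_length_um: 30000.0      # 3 cm
drive:
  vpp: 8.0
  frequency_hz: 1.0e+7
medium:
  permittivity_f_per_m: 7.1e-10
  conductivity_s_per_m: 1.5       # typical neuronal culture media
  viscosity_pa_s: 1.0e-3
  density_kg_per_m3: 1000.0
cell:
  model: shelled
  radius_um: 5.0
  density_kg_per_m3: 1050.0
  membrane_thickness_nm: 5.0      # lipid-bilayer scale
  membrane_permittivity_f_per_m: 1.8e-12
  membrane_conductivity_s_per_m: 1.0e-7
  cytoplasm_permittivity_f_per_m: 7.1e-10
  cytoplasm_conductivity_s_per_m: 0.75
  relative_permittivity: 80.0     # homogeneous-model alternative
  conductivity_s_per_m: 0.1       # homogeneous-model alternative
flow:
  volumetric_rate_ul_min: 2.5
  enabled: false                  # trap scenario is quiescent; enable for hold-against-flow
gravity:
  enabled: false                  # DEP-only trajectory model; enable for settling studies
grid:
  spacing_um: 0.5
  solver_tolerance: 1.0e-8
  max_iterations: 10000
integration:
  dt_s: 1.0e-4
  t_end_s: 2.0
  snapshot_times_s: [0.3, 1.0, 2.0]
  export_stride: 100
ensemble:
  count: 50
  seed: 42
  x_um: [-120.0, 120.0]
  y_um: [0.0, 0.0]
  z_um: [5.0, 35.0]
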