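# Full-scale CE-DBT configuration: clinical working resolution
# (85 um native pitch x 8 = 680 um voxels, 188 x 417 x 175 grid).
# Several-hour runtime on one core; the desk-scale defaults in
# cedbt.PipelineConfig are the test configuration.
geometry:
  n_views: 25
  arc_span: 50.0
  source_to_detector_distance: 650.0
  rotation_axis_height: 47.0
  detector_pitch: 0.68
  detector_shape: [620, 352]   # rows (y, source travel) x cols (x)
grid:
  shape: [188, 417, 175]
  voxel_size: 0.68
  origin: [-63.58, -141.44, 0.34]
recon_params:
  alpha: 1.75
  beta: 0.1
  epsilon_rmse: 0.01
  n_iterations: 1000
  step_ratio: 0.05
  seed: 0
filter_spec:
  padding_factor: 2.0
  dc_handling: kernel
  filter_axis: y
  window: none
methods: [dtv, fbp]
poly_degree: 8
mask_method: fraction_of_median
mask_param: 0.2
irls:
  max_iter: 50
  tol: 1.0e-08
  delta_scale: 1.0e-06
background_floor: 0.05
subtraction_w: null   # null -> sweep with background-variance minimization
simulate: true
phantom:
  slab_thickness: 40.0
  insert_diameters: [2.0, 3.0, 5.0, 8.0]
  iodine_concentrations: [1.0, 2.0, 3.0, 5.0]
  glandular_fraction: 0.5
  texture_scale_mm: 5.0
  insert_shape: sphere
  seed: 0
noise:
  fluence: 2.0e+08
  seed: 0
output_dir: cedbt_full_run
seed: 0
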