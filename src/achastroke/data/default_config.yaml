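atlas_shape:
  acha_col_offset_frac: 0.12
  acha_radius_frac: 0.04
  acha_row_offset_frac: 0.15
  cortex_inner_frac: 0.68
  hemisphere_col_frac: 0.45
  hemisphere_row_frac: 0.42
  mca_half_angle_deg: 40.0
  mca_inner_frac: 0.25
cohort:
  acha_patent_factor: 1.2
  acha_residual_fraction: 0.1
  achao_1h: 2
  achao_2h: 1
  achao_permanent: 7
  baseline_cbv_mean: 4.0
  baseline_cbv_sd: 0.3
  cortical_fraction_achao: 0.5896193771626298
  cortical_fraction_no_achao: 0.3325526932084309
  cortical_fraction_sd: 0.05
  hemisphere_volume_mm3: 600.0
  mca_residual_fraction: 0.3
  n_1h: 8
  n_2h: 7
  n_permanent: 13
  noise_sd: 0.4
  occluded_side: right
  pmcao_achao:
    mean: 144.5
    sd: 11.72
  pmcao_no_achao:
    mean: 42.7
    sd: 27.62
  section_positions:
  - 5.7
  - 3.7
  - 1.7
  - -0.3
  - -2.3
  - -4.3
  - -6.3
  - -8.3
  section_spacing_mm: 2.0
  swelling_fraction: 0.1
  temp_achao:
    mean: 94.83333333333333
    sd: 41.58
  temp_no_achao:
    mean: 15.549999999999997
    sd: 23.38
  vessel_count: 5
  vessel_value: 15.0
  weight_range_g:
  - 300.0
  - 500.0
duration_coding: hours24
grid:
  bregma_levels:
  - 0.0
  - -2.4
  n_cols: 128
  n_rows: 128
  pixel_size: 0.09765625
  slice_thickness: 2.4
probability_map_levels:
- -0.3
- -2.3
screen_alpha: 0.1
seed: 0
t_variant: pooled
tolerance_voxels: 0
vessel_threshold: 10.0
write_images: false
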