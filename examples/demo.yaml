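baseline: 12.0
cells_per_field: 40
chrom_lengths:
- 10
- 10
- 10
- 10
- 10
- 10
- 10
- 10
- 10
- 10
- 10
- 10
- 10
- 10
- 10
fdr_ceiling: 0.12
field_shape:
- 320
- 320
frac_fluorescent: 0.8
image_noise_sd: 20.0
missing_rate: 0.002
n_fields: 8
n_perm: 100
n_segregants: 120
noise_sd: 2.0
out_dir: demo_run
pixel_size: 0.2
prune:
  maf_min: 0.25
  max_missing: 1
  r2_max: 0.9
qtl:
- - 52
  - 10.0
- - 127
  - -8.0
recomb_prob: 0.2
seed: 0
segmentation:
  fluor_threshold: null
  focus_guard_px: 2
  highpass_scale: 0.8
  keep_border_cells: true
  local_offset_k: 1.25
  local_window: 61
  lowpass_scale: 1.2
  max_cell_area: 80.0
  min_cell_area: 4.0
  min_focus_area: 0.1
  puncta_max_diameter: 2.0
  puncta_offset_k: 5.0
  puncta_smooth_px: 1.0
  puncta_window: 31
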