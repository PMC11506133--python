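# Embryonic-stage oligomer sizing scenes:
#  * on_fibril — secondary oligomers (7.9 +/- 0.2 nm) adsorbed on primary
#    fibrils, measured via stacked-support subtraction;
#  * on_gold — primary-pathway oligomers (7.3 +/- 1.9 nm, broad) deposited
#    directly on the substrate;
#  * secondary_10min — first secondary fibrils (length 250 +/- 55 nm,
#    diameter 6.5 +/- 0.2 nm) riding on primary fibrils, ~10 min stage.
scenes:
  - name: on_fibril
    replicates: 3
    time_min: 0.5
    field_nm: [2000, 2000]
    pixel_size_nm: 2.0
    substrate_sigma_nm: 0.12
    primary_fibrils:
      count: 16
      diameter_mean_nm: 8.3
      diameter_sd_nm: 0.85
      length_mean_nm: 842.0
      length_sd_nm: 133.5
      persistence_nm: 8000.0
    oligomers:
      count: 40
      diameter_mean_nm: 7.9
      diameter_sd_nm: 0.2
      p_edge: 0.5
      p_backbone: 0.5
      p_substrate: 0.0
    tip:
      shape: paraboloid
      radius_nm: 2.0
    artifacts:
      line_offset_sigma_nm: 0.8
      tilt_nm_per_um: [4.0, 6.0]
      pixel_noise_sigma_nm: 0.25
  - name: on_gold
    replicates: 1
    time_min: 0.5
    field_nm: [2000, 2000]
    pixel_size_nm: 2.0
    substrate_sigma_nm: 0.12
    primary_fibrils:
      count: 0
    oligomers:
      count: 250
      diameter_mean_nm: 7.3
      diameter_sd_nm: 1.9
      p_edge: 0.0
      p_backbone: 0.0
      p_substrate: 1.0
    tip:
      shape: paraboloid
      radius_nm: 2.0
    artifacts:
      line_offset_sigma_nm: 0.8
      tilt_nm_per_um: [4.0, 6.0]
      pixel_noise_sigma_nm: 0.25
  - name: secondary_10min
    replicates: 3
    time_min: 10.0
    field_nm: [2000, 2000]
    pixel_size_nm: 2.0
    substrate_sigma_nm: 0.12
    primary_fibrils:
      count: 14
      diameter_mean_nm: 8.3
      diameter_sd_nm: 0.85
      length_mean_nm: 842.0
      length_sd_nm: 133.5
      persistence_nm: 8000.0
    secondary_fibrils:
      count: 10
      diameter_mean_nm: 6.5
      diameter_sd_nm: 0.2
      length_mean_nm: 250.0
      length_sd_nm: 55.0
      corrugation_amplitude_mean_nm: 1.0
      corrugation_amplitude_sd_nm: 0.2
      corrugation_wavelength_nm: 80.0
      stacked_on_primary: true
    oligomers:
      count: 0
    tip:
      shape: paraboloid
      radius_nm: 2.0
    artifacts:
      line_offset_sigma_nm: 0.8
      tilt_nm_per_um: [4.0, 6.0]
      pixel_noise_sigma_nm: 0.25
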