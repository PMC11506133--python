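# Growth-phase scenes:
#  * growth_180min — mature secondary fibrils (length 2200 +/- 145 nm) on a
#    larger field to avoid border truncation; corrugated, so the Rq
#    fingerprint classifies them secondary;
#  * oligomer_20min — enlarged secondary oligomers (11.9 +/- 0.3 nm)
#    adsorbed on primary fibrils.
scenes:
  - name: growth_180min
    replicates: 2
    time_min: 180.0
    field_nm: [3200, 3200]
    pixel_size_nm: 2.0
    substrate_sigma_nm: 0.12
    primary_fibrils:
      count: 0
    secondary_fibrils:
      count: 12
      diameter_mean_nm: 9.0
      diameter_sd_nm: 0.5
      length_mean_nm: 2200.0
      length_sd_nm: 145.0
      persistence_nm: 20000.0
      corrugation_amplitude_mean_nm: 4.6
      corrugation_amplitude_sd_nm: 0.5
      corrugation_wavelength_nm: 90.0
      stacked_on_primary: false
    oligomers:
      count: 0
    tip:
      shape: paraboloid
      radius_nm: 2.0
    artifacts:
      line_offset_sigma_nm: 0.8
      tilt_nm_per_um: [4.0, 6.0]
      pixel_noise_sigma_nm: 0.25
  - name: oligomer_20min
    replicates: 2
    time_min: 20.0
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
    oligomers:
      count: 36
      diameter_mean_nm: 11.9
      diameter_sd_nm: 0.3
      p_edge: 0.3
      p_backbone: 0.7
      p_substrate: 0.0
    tip:
      shape: paraboloid
      radius_nm: 2.0
    artifacts:
      line_offset_sigma_nm: 0.8
      tilt_nm_per_um: [4.0, 6.0]
      pixel_noise_sigma_nm: 0.25
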