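# Two-class roughness fingerprint scene: smooth primaries (Rq ~0.7-1.7 nm)
# and strongly corrugated secondaries (Rq ~2.8-4.5 nm) in one field.
# Corrugation amplitude encodes target Rq x sqrt(2); the secondary base
# diameter is raised to 10 nm so corrugation troughs stay above the
# segmentation threshold.
scenes:
  - name: roughness
    replicates: 2
    time_min: 240.0
    field_nm: [2000, 2000]
    pixel_size_nm: 2.0
    substrate_sigma_nm: 0.12
    primary_fibrils:
      count: 8
      diameter_mean_nm: 8.3
      diameter_sd_nm: 0.85
      length_mean_nm: 842.0
      length_sd_nm: 133.5
      persistence_nm: 8000.0
      corrugation_amplitude_mean_nm: 1.7
      corrugation_amplitude_sd_nm: 0.35
      corrugation_wavelength_nm: 80.0
    secondary_fibrils:
      count: 8
      diameter_mean_nm: 10.0
      diameter_sd_nm: 0.5
      length_mean_nm: 900.0
      length_sd_nm: 150.0
      persistence_nm: 8000.0
      corrugation_amplitude_mean_nm: 5.8
      corrugation_amplitude_sd_nm: 0.6
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
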