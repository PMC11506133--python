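# Primary-fibril reference population: mature seeding-layer fibrils,
# diameter 8.3 +/- 0.85 nm, length 842 +/- 133.5 nm, submonolayer coverage.
# 6 replicate frames x 17 fibrils >= 100 fibrils per study run.
scenes:
  - name: primary
    replicates: 6
    field_nm: [2000, 2000]
    pixel_size_nm: 2.0
    substrate_sigma_nm: 0.12
    primary_fibrils:
      count: 17
      diameter_mean_nm: 8.3
      diameter_sd_nm: 0.85
      length_mean_nm: 842.0
      length_sd_nm: 133.5
      persistence_nm: 8000.0
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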