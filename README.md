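# afmquant

Quantification of amyloid fibril and oligomer morphometry from AFM height
maps, together with a calibrated synthetic topograph simulator that makes
every measurement verifiable against ground truth.

The pipeline reproduces the analysis workflow used to characterise
fibril-surface (secondary) nucleation from liquid-AFM topographs:

* **simulate** — render scenes of cylindrical fibrils (optionally with
  longitudinal corrugation and stacked "rider" fibrils) and spherical
  oligomers placed on fibril edges, backbones or the bare substrate; apply
  tip convolution (grayscale dilation by a paraboloid or sphere-capped-cone
  probe) and scan artifacts (per-scanline offsets, tilt, substrate
  roughness, pixel noise);
* **preprocess** — per-scanline polynomial flattening with iterative object
  masking, and a robust substrate baseline that all heights refer to;
* **trace & measure** — segmentation, sub-pixel backbone tracing, arc
  length, diameter as the trimmed mean apex height above the local support,
  oligomer sizing from 3–5 sectional profiles, and stacked-object height
  subtraction (object height minus host fibril apex);
* **classify** — adsorption site (edge / backbone / substrate), fibril
  generation by windowed RMS roughness (Rq) along the backbone, and
  catalytic activity (dormant / active / superspreader) from the linear
  density of adsorbed secondary objects;
* **report** — population statistics (mean ± population SD, fixed-width
  histograms) and growth curves over time.

Conventions: all heights and lengths are in nanometres; grids are row-major
with the origin at the top-left pixel and physical coordinates at pixel
centres; apex height above the support equals the diameter for spheres and
surface-lying cylinders; heights (unlike widths) are insensitive to tip
geometry, which is why all sizing is height-based.

## File formats

Height maps are single-channel float32 TIFFs with a JSON metadata sidecar
(same stem, `.json`): pixel size, acquisition time, frame id, generator
seed.  Ground truth is JSON; measurement tables are CSV with a fixed column
order (`frame_id, time_min, object_id, class, diameter_nm, length_nm,
rq_nm, site, activity, host_id`) and deterministic row order; scene configs
are YAML.

## CLI

```bash
# render scenes (TIFF + sidecar + ground-truth JSON per frame)
afmquant simulate --config fixtures/fig2_primary.yaml --seed 42 --out out/

# measure fibrils and oligomers in height maps
afmquant analyze out/*.tif --out measurements.csv --summary-out frames.json \
    --flatten-order 1 --edge-window-nm 20 --rq-threshold-nm 2.35

# aggregate into population statistics and growth curves
afmquant report --in measurements.csv --out summary.json
```

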