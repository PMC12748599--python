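# borealdist

Detection and classification of forest disturbances — insect defoliation by
severity, wildfire, harvesting, windthrow and water extension — in annual
6-band (blue, green, red, NIR, SWIR1, SWIR2) spectral time series.

The pipeline is a two-step hybrid:

1. **Temporal segmentation** of the per-pixel NBR series into piecewise-linear
   segments (greedy hinge-basis knot insertion with an F-test stop and local
   knot refinement). Declining runs whose cumulative fitted drop reaches 0.1
   become candidate disturbance segments; up to the 5 most recent are kept,
   and segments shorter than 10 years go on to classification.
2. **Temporal CNN classification** of a 10-year × 6-band window anchored one
   year before the detected break (conv blocks with 64 filters, kernel 3,
   dropout 0.4; dense 64; softmax over 18 training classes; Adam, 50 epochs,
   batch 64, weight decay 1e-5, decaying learning rate from 1e-3). The CNN is
   implemented in pure numpy — no deep-learning framework required.

Predicted classes are remapped to map codes 0–8 and assembled into per-pixel
annual disturbance series: rapid classes (wildfire 1, harvesting 2,
windthrow 3, water extension 4) are stamped at a single year (wildfire
segments stretched past 2 years stamp their end year), pest classes (5–8)
across their whole segment. Post-processing offers a 12-pixel sieve filter on
a ±2-year union mask and a wetland filter. A synthetic trajectory/scene
simulator makes every stage testable offline, and a validation module covers
confusion matrices, omission/commission, stratified area-adjusted accuracy
with standard errors, plot-level percent-AGB-defoliated, majority-of-9
extraction, temporal agreement and stratified sample planning.

## Layout

| module | contents |
| --- | --- |
| `spectral` | `AnnualSpectra`, NBR, decline-positive dNBR, severity classes |
| `simulate` | class-conditional trajectory and scene simulator |
| `training` | candidate filtering, window construction, composite classes, class remapping, spatial CV splits |
| `segmentation` | piecewise-linear fitting and disturbance-segment extraction |
| `tempcnn` | the numpy temporal CNN: build, train, cross-validate, predict |
| `assembly` | inference windows, annual series assembly, latest products, sieve/wetland filters |
| `validation` | accuracy statistics and ground-plot analysis |
| `io`, `cli`, `pipeline` | raster/table I/O, configuration, CLI, end-to-end glue |

## CLI

All subcommands honour `--config <yaml>` (see `borealdist.io.PipelineConfig`)
and `--seed`:

```bash
borealdist simulate --out scene/                       # labeled demo scene
borealdist make-training --out train.npz               # simulated windows
borealdist train --training train.npz --model-out model.npz [--cv]
borealdist detect --stack scene/ --out segments.csv    # segmentation only
borealdist map --stack scene/ --model model.npz --out products/
borealdist postprocess --products products/ --out filtered/
borealdist validate [--matrix counts.csv]              # accuracy report
```

Products follow the published naming: `annual_<year>.tif` coded rasters,
`latest_type.tif` / `latest_year.tif` / `ending_year.tif`, and
`legend_type.csv`; georeferencing passes through a `georef.json` sidecar.

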