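# File formats

All files are plain text (CSV, Newick, JSON, YAML).

## Occurrence CSV

One row per georeferenced occurrence point ("locality"), columns:

| column  | type  | units | meaning |
|---------|-------|-------|---------|
| species | str   | —     | species identifier; matched to tree tips after trimming whitespace and replacing spaces with underscores |
| lon     | float | decimal degrees | longitude, [-180, 180] |
| lat     | float | decimal degrees | latitude, [-90, 90] |
| region  | str   | —     | region label (e.g. Africa / Asia / Oceania); optional for single-region analyses |
| bio1    | float | °C    | annual mean temperature |
| bio5    | float | °C    | max temperature of warmest month |
| bio6    | float | °C    | min temperature of coldest month |
| bio12   | float | mm    | annual precipitation |
| bio16   | float | mm    | precipitation of wettest quarter |
| bio17   | float | mm    | precipitation of driest quarter |

Row invariants: `bio6 <= bio1 <= bio5` and `0 <= bio17 <= bio16 <= bio12`.
Rasters that store temperature as °C×10 can be ingested with
`--temp-scale 10` (`nichebreadth qc`).

## Tree (Newick)

Rooted, branch lengths mandatory on every non-root edge; polytomies allowed;
need not be ultrametric.

## QC report CSV

One row per QC decision: `row, species, status, method, variable, value,
threshold` with status `kept | duplicate | outlier | out_of_range`; outlier
rows carry the screen (`iqr` or `jackknife`), the offending variable, its
value, and the violated threshold (IQR fences, or the critical gap).

## Niche summary CSV

One row per species×region plus one pooled row per species
(`region == "global"`): `species, region, n_localities, temp_position,
precip_position, tnb, pnb_annual, pnb_wetdry, tnb_wl, pnb_wl, tnbr_wl_s,
pnbr_wl_s, tnpv, pnpv`.  Temperatures in °C (variances °C²), precipitation
in mm (variances mm²); ratios dimensionless in (0, 1].

## Fit table CSV

One row per PGLS model × stratum: `model, region, n, lambda, r2, p, slope,
intercept, pnb_index, converged, degenerate`.  The ratio summary table has
`region, n, tnbr_mean, tnbr_min, tnbr_max, pnbr_mean, pnbr_min, pnbr_max`.

## Pipeline config (YAML or JSON)

See `examples/config.yaml`.  Top-level keys mirror
`nichebreadth.pipeline.AnalysisConfig`; `sim_params` mirrors
`nichebreadth.synthetic.ClimateFieldParams`.

## Manifest (JSON)

Written by `run-all`: package version, seed, full config echo, per-stage row
counts, and all warnings raised during the run.  `sim_truth.json` (simulation
mode) records the generator's ground truth per species plus indices of any
injected outlier/duplicate rows.
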