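# upwell

Analysis toolkit for interannual productivity variability in
eastern-boundary upwelling systems, exercised end-to-end on synthetic
gridded fields with known ground truth.

Stages (one module each under `src/upwell/`):

| module        | what it does |
|---------------|--------------|
| `grids`       | gridded monthly fields (NetCDF I/O), regions (boxes, coastal bands), cos-lat area means, wind-stress curl, along-path extraction |
| `synth`       | synthetic fields/budgets: seasonal cycle, pointwise trends, AR(1) noise, injected multi-month extremes, a propagating coastal sea-level pulse, exactly-closing budget terms |
| `anomalies`   | pointwise detrending + deseasonalization (joint removal), per-calendar-month std, seasonal means |
| `events`      | extreme-event detection (±k·σ threshold, minimum duration), peak-season filtering, summaries |
| `composites`  | lag composites keyed to event peaks; bootstrap-without-replacement significance (2.5th–97.5th percentile masking) |
| `heat_budget` | mixed-layer budget bookkeeping, closure residual, flux/depth (Q′/H′) decomposition, contribution percentages |
| `indices`     | basin-difference multidecadal SST index, equatorial-Pacific index with 3-month running mean, sliding-window Pearson correlation, critical r |
| `waves`       | Hovmöller construction, brick-wall FFT high-pass (10-year cutoff), 1-2-1 smoothing, propagation-lag estimation |
| `pipeline`/`cli` | orchestration, manifests, deterministic reruns |

## CLI

```bash
upwell run --out rundir/ --seed 7          # full synthetic pipeline
upwell synth --seed 3 --out data/          # fields + truth sidecar
upwell anoms --in data/npp.nc --var npp --out anoms.nc --region CDNI
upwell events --in rundir/cdni_nppa.csv --k 0.8 --min-duration 2 --out ev.csv
upwell composite --in rundir/cdni_nppa.csv --events ev.csv --nboot 10000 \
    --seed 7 --out comp.csv
upwell budget --q q.csv --h h.csv --out qh.csv
upwell indices amv --in data/sst.nc --out amv.csv
upwell correlate --x a.csv --y b.csv --window 21 --out corr.csv
upwell hovmoeller --in data/sla.nc --var sla --band 1.0 --out hov.csv
```

Exit codes: 0 ok, 2 configuration error, 3 data error. `upwell run` writes
a `manifest.json` with SHA-256 hashes of every artifact; identical config
and seed reproduce identical hashes.

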