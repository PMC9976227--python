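# supplynet

Characterization of directed agricultural trade networks and scoring of
external supply risk for importing countries.

The pipeline takes long-format bilateral trade flows (exporter, importer,
USD, year) plus per-country GDP and epidemic-risk (CRI) indicators, and
produces:

* **Networks** — a dense weighted matrix per year (row = exporter,
  column = importer) and a binary adjacency thresholded at a configurable
  cutoff (default 100 million USD, inclusive).
* **Metrics** — directed density `E/(n(n-1))`, in/out degree tables,
  per-country trade shares with top-k cumulative concentration, and
  least-squares exponential fits to the empirical degree distribution.
* **Communities** — modularity on the symmetrized graph, a seeded Louvain
  implementation (best-gain local moves + aggregation, with deterministic
  restarts and iterated-local-search perturbation for quality), and
  "absolute dependence" pairs (importers drawing ≥ θ of their imports from
  one supplier, θ default 0.5).
* **Risk scores** — per importer: EDI (imports/GDP + 1), HHI (sum of squared
  supplier shares), RICI (import-share-weighted supplier CRI, or the
  importer's own CRI in `own_cri` mode), the AECSI composite (raw sum or sum
  of graded scores), contribution rates, five-level grades via Fisher–Jenks
  natural breaks or equal intervals, and a dominant-risk label
  (component with contribution > 50%, else "Compound risks").
* **Synthetic worlds** — gravity-model flow generators with Pareto country
  masses, pre-epidemic (CRI ≡ 1) and epidemic (log-normal CRI) regimes, and
  threshold calibration to a target density, so every stage runs with no
  external data.

A small bundled reference table (`supplynet.reference`) carries the published
top-10 exporter/importer rows, grand totals and connection counts for the
88-country 2019/2021 sample, used to recompute the published concentration
and density figures.

## Command line

```sh
# end-to-end on a synthetic two-year world (pre-epidemic 2019, shocked 2021)
supplynet all --years 2019,2021 --n-countries 100 --seed 7 --outdir out/

# individual stages / real data
supplynet simulate --years 2019 --n-countries 50 --outdir data/
supplynet risk --flows data/flows.csv --indicators data/indicators.csv \
    --years 2019 --classifier jenks --rici-mode partner --outdir out/
```

Input dialects: flows `year,exporter_iso3,importer_iso3,value_usd`;
indicators `iso3,year,gdp_usd,cri`. Outputs per year: `metrics.json`,
`degrees.csv`, `edges.csv`, `shares_{export,import}.csv`, `partition.csv`,
`communities.json`, `dependence.csv`, `risk.csv`, `breaks.json`; plus a
run `manifest.json` (config hash, stage statuses; reruns are bit-identical)
and a two-year `change_report.json` (Δdensity, Δedges, mean AECSI,
grade-migration counts).

A YAML file mirroring `supplynet.cli.RunConfig` can be passed with
`--config`; explicit flags override it.

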