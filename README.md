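# clusterlab

Benchmarking apparatus for K-means centroid initialization. The package
implements batch (Lloyd-sweep) K-means together with three hybrid
initialization strategies — a minimum-spanning-tree skeleton selector, a
genetic search over data-row centroid sets, and an agglomerative tree cut —
plus three baseline clusterers (hierarchical, DBSCAN, EM Gaussian mixture),
eleven cluster-validity indices, optimal-k selection by majority vote of
silhouette / gap statistic / elbow, and a two-phase study pipeline that
emits machine-readable comparison reports.

## Layout

| module                    | contents |
|---------------------------|----------|
| `clusterlab.datasets`     | delimited-table loading, z-scoring (sample SD), the seven benchmark profiles |
| `clusterlab.synthetic`    | seeded Gaussian-mixture generators emulating the benchmark profiles |
| `clusterlab.kmeans`       | batch K-means, SSE objective, random init, best-of-restarts |
| `clusterlab.initializers` | Prim MST + skeleton/maxi-min init, GA init, hierarchical init |
| `clusterlab.baselines`    | agglomerative, DBSCAN (auto-eps knee), EM mixture |
| `clusterlab.validity`     | silhouette, Dunn, RPT, RI/ARI, accuracy, F-measure, Hubert's Γ, MI/VI, `select_k` |
| `clusterlab.pipeline`     | Phase I / Phase II drivers, study runner, JSON + TSV reports |

## CLI

Generate a synthetic stand-in for a benchmark profile:

```sh
synth --profile wine --separation 3 --seed 7 --out wine_synth.csv
```

Cluster one table with a chosen initializer (`random`, `mst`, `ga`, `hier`);
`--k auto` runs the 2–15 majority-rule search:

```sh
clusterlab run --input wine_synth.csv --label-column class \
    --k auto --init mst --seed 42 --out report.json
```

Run the full two-phase study from a YAML config:

```sh
clusterlab study --config study.yaml --out-dir reports
```

Example `study.yaml`:

```yaml
seed: 42
restarts: 25
k: auto          # or a fixed integer
ga: {pop_size: 50, generations: 100}
datasets:
  - {name: iris, source: bundled}        # scikit-learn's iris/wine
  - {name: wine, source: bundled}
  - {name: glass, source: synthetic, separation: 3.0}
  - {name: mydata, source: csv, path: mydata.csv, label_column: class}
```

Each dataset yields `<name>.json` (validated against
`src/clusterlab/schema/study_report.schema.json`) and `<name>.tsv` with the
columns `I SSE Si RPT Dunn RI ARI AC F HI VI`.

## Notes

- Standardization uses the sample (n−1) standard deviation; this fixes the
  SSE scale of all reported numbers.
- RPT is a stability-weighted silhouette, `Si * (1 + S̄)`, where `S̄` is the
  mean Rand agreement between the partition and re-clusterings of bootstrap
  resamples.
- Labels are only ever consumed by the external validity indices, never by
  any clustering routine.
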