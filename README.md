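# morphoscreen

Morphological-profiling analysis for cell-culture **media-optimization
screens**. The package is aimed at analysts of plate-based high-content
screens (e.g. Cell Painting of mesenchymal stromal cells grown in
candidate chemically defined media) who start from a CellProfiler-style
per-cell feature table and need a reproducible route from raw single-cell
features to a ranked list of media "hits".

It provides, as one tested pipeline:

- **Design** — two-level full-factorial enumeration (2^k formulations for
  k growth factors) and seeded semi-random 96-well plate layouts with
  on-plate controls (12 SCM + 12 CDBM negative-control wells, 4
  positive-control wells, 4 replicate wells per treatment).
- **Synthetic screens** — a generator with planted ground truth
  (per-condition proliferation multiplier *m* and phenotype shift δ along
  a fixed direction), so every stage is testable without imaging data.
- **Profiling** — per-well median aggregation; per-plate MAD
  normalization to negative controls, `x' = (x − median_CTL)/MAD_CTL`;
  removal of features with |Pearson r| > 0.9; correlation-mode PCA
  retaining the components that explain 90% of the variance.
- **Statistics** — the **mp-value** (multidimensional perturbation
  value): PC scores weighted by explained-variance ratios, Mahalanobis
  distance between group centroids under the pooled covariance, and a
  label-permutation p-value
  `mp = (1 + #{D_perm ≥ D_obs}) / (N_perm + 1)`, enumerated exhaustively
  when the number of distinct splits is small (4 vs 12 wells →
  C(16,4) = 1820); Dunnett many-to-one count comparisons; replicate CV.
- **Hit calling** — potential hits (CV < 0.2, significantly higher
  proliferation than both negative controls, significant mp-value against
  both), Ward clustering of potential-hit wells in refit PC space, final
  hits (all replicates in one cluster, highest count per cluster), and
  representative-well selection by cell-shape features.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/05_full_screen_hit_calling.py` simulates a 32-condition
screen (2 plates) with three planted hits and calls them end to end:

```
planted hits:   ['T03', 'T06', 'T25']
potential hits: ['T03', 'T06', 'T25']
final hits:     ['T03', 'T06', 'T25']
  T03: mean count 271, CV 0.034, representative well P1/C8
  T06: mean count 233, CV 0.046, representative well P1/H1
  T25: mean count 230, CV 0.033, representative well P2/H9
```

All three planted formulations — and no null formulation — pass every
criterion and survive cluster-based final selection; the representative
well is the replicate closest to the hit's mean cell-shape profile.

The same pipeline is scriptable from the shell:

```sh
morphoscreen run --out demo_out/          # bundled demo configuration
morphoscreen design --factors factors.yaml --seed 0 --out out/
morphoscreen validate --cells cells.csv --platemap out/platemap.csv
```

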