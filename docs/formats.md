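# File formats

## Run configuration (YAML or JSON)

One flat schema shared by the CLI and the library; unknown keys are
rejected by name. All keys are optional — defaults reproduce the reference
conditions (1500 cells, 25% outer, dt 0.2, T 150, positional noise 0.02).

```yaml
mode: two_type            # or "grn"
population:
  n_cells: 1500
  outer_fraction: 0.25
  cell_radius: 1.0
  packing_fraction: 0.5
  seed: 0
mechanics:
  alpha_ii: 0.75          # adhesion balance factors, in (0, 1)
  alpha_oo: 0.75
  alpha_io: 0.75
  beta_ii: 0.0            # directed long-range strengths (signaler->responder)
  beta_oo: 0.0
  beta_io: 0.0
  beta_oi: 0.0
  k_s: 1.0
  cutoff_factor: 1.0
  p: 2.0                  # long-range decay exponent
  dt: 0.2
  t_total: 150.0
  gamma: 1.0
  noise_sigma: 0.02
  noise_mean: 0.0
outputs:
  directory: "."
  record_every: 0         # 0 = final state only
  format: csv             # csv or ply
grn: {}                   # GRNSpec document, only in grn mode (see below)
```

## GRN specification document

Produced/consumed by `gastrosim.io.grn_spec_to_dict` /
`grn_spec_from_dict`; embeds in the run config under `grn`.

```yaml
n_genes: 3
edges:
  - {source: 0, target: 0, weight: 1.0, type: intra}
  - {source: 0, target: 1, weight: 0.15, type: inter, lambda: 2.0,
     gate: {gene: 0, op: above, theta: 0.5}}
amplitude: [0.142, 0.5, 0.5]
hill_h: [8, 4, 4]
hill_k: [0.7, 0.7, 0.7]
leak: [0.0, 0.01, 0.01]
degradation: [0.15, 0.2, 0.2]
gene_noise_sigma: 0.01
readout:
  timer_gene: 0
  timer_threshold: 0.5
  class_gene: 1
  class_threshold: 0.5
  alpha_hom: 0.80
  alpha_ii: 0.72
  alpha_oo: 0.79
  alpha_io: 0.88
  beta: {"o->o": 0.3}
  p: 2.0
```

## Population snapshot CSV

Columns: `id, x, y, z, radius, type, gene_1..gene_G` (gene columns present
only for genetically regulated populations). Types are `o` (outer), `i`
(inner), `u` (undifferentiated). Lossless round-trip via
`CellPopulation.to_csv` / `from_csv`.

## PLY point cloud

ASCII PLY with per-vertex `x, y, z, radius`, integer `type_code`
(o = 0, i = 1, u = 2) and one float property per gene; loadable in standard
3D viewers.

## Sweep result CSV

One row per grid point: `point_index`, the three α values, `channel`
(`none` or e.g. `o->o`), `sign`, `magnitude`, `beta`, `mean_A`, `mean_L`,
`error`, plus per-replicate `A_rep{k}`, `L_rep{k}`, `seed_rep{k}` columns.

## Metrics CSV

`gastrosim simulate` writes one row per recorded snapshot:
`step, L, A` (shape descriptor columns appear when requested through the
library's `PatternMetrics.to_row`).

## Run manifest JSON

Written next to every CLI output: `schema_version`, tool name and version,
creation time, wall-clock seconds, every seed consumed, and the full
validated config — sufficient to regenerate the run exactly.
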