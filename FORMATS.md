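# File formats

All matrices are plain delimited text; all metadata is JSON or YAML.

## Cohort directory

Written by `refusion simulate` / `analysis/01_simulate_cohort.py`, read by
`refusion fuse|replicate` and `refusion.io.read_cohort`.

| file | contents |
|---|---|
| `<MOD>.csv` (e.g. `FC.csv`, `FA.csv`, `GMV.csv`) | subjects x features matrix; header row of feature ids; first column `subject_id`. Any `*.csv` with a `subject_id` column that is not one of the reserved names below is treated as a modality. |
| `phenotype.csv` | `subject_id, group` (1 = patient, 0 = control) plus covariates (`age`, `sex`, `meanFD`) and clinical scores (`onset_age`, `MMSE`, `HSCT`; missing values allowed in clinical columns). |
| `reference.csv` | `subject_id, beta` — the per-subject reference value (methylation beta at the target CpG). Missing (empty/NaN) entries mark subjects without reference data; the pipeline drops them. |
| `methylation.csv` | optional; `subject_id, group, <locus ids...>` beta-value matrix. |
| `truth.json`, `truth_sources_<MOD>.csv`, `truth_loadings_<MOD>.csv` | synthetic ground truth (generator config, target component index, per-modality sources and loadings). |
| `manifest.json` | run manifest (below). |

Subject order in every matrix must match `phenotype.csv`; `read_cohort`
re-aligns by `subject_id` and the pipeline re-checks the order.

## Results directory (`refusion fuse`)

| file | contents |
|---|---|
| `component_statistics.csv` | one row per (component, modality): `t, p, q, r_ref, p_ref, q_ref, r_partial, p_partial, selected`. FDR family = components x modalities. |
| `maps_<MOD>.csv` | final joint component maps, components x features. |
| `zmaps_<MOD>.csv` | z-scored maps (rows = components). |
| `loadings_<MOD>.csv` | subject loadings; first column `subject_id`. |
| `fusion_summary.json` | selected component, lambda, order, convergence flags, objective value, top-component inter-set correlations. |
| `manifest.json` | run manifest. |

## Replication directory (`refusion replicate`)

`similarity_<MOD>.csv` (runs x runs matrix of absolute spatial
correlations between selected maps), `overlap_<MOD>.csv` (0/1 vector:
features surviving the z-threshold in at least two runs),
`replication_report.json`, `manifest.json`.

## Run manifest

`manifest.json`: software name/version, Python version, master seed,
config snapshot, SHA-256 checksums of all input files, stage timings,
convergence flags.  Re-running with an identical manifest reproduces
identical outputs.

## Config file (YAML, flat key-value)

Keys mirror the `SimulationConfig` and `FusionConfig` field names, e.g.

```yaml
n_patients: 33
n_controls: 40
features_per_modality: [300, 250, 200]
rho_ref: -0.4
group_effect_d: 0.8
seed: 1
n_components: 5        # or omit and pass --n-components auto
lambda: 0.5            # alias for lam
methylation_n_loci: 1000
methylation_delta: 0.06
```

## NIfTI import/export

FA/GMV voxel features can be read from 3-D NIfTI volumes plus a binary
NIfTI mask (`refusion.io.nifti_to_features`); the mask defines feature
order as ascending linear index with x fastest.  `refusion export-nifti`
writes a component map back into the mask's grid.
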