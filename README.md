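# sxc

Comparative Shapley-value analysis of random forest (RF) and
Tanimoto-kernel SVM binary compound classifiers on binary fingerprints.

The package trains both model families on identical balanced training sets
of increasing size, computes **exact** Shapley values for every fingerprint
position (present *and* absent bits) — via a closed-form engine for the
Tanimoto-kernel SVM decision function and an exact interventional
tree-traversal engine for RF probabilities — and aggregates them into
prediction patterns, instance-/feature-based cumulative Shapley values,
feature contribution scores (f_cs), PCC-based feature-contribution
patterns, top-k feature intersections, and atom-level substructure maps.

By default everything runs on synthetic fingerprint data with *planted*
class-discriminative bits, so every stage can be validated against a known
ground truth (and against a brute-force Shapley enumeration oracle).
An optional real-molecule mode (`sxc.fingerprints`, requires RDKit) hashes
SMILES to 2048-bit layered-atom-environment fingerprints with bit→atom maps.

## Layout

| module | contents |
| --- | --- |
| `sxc.synthetic` | planted-bit fingerprint generator, activity-record fixtures, CSV/MTX/JSON IO |
| `sxc.curation` | record filters (confidence, mass, potency, flags) and similarity-based class selection |
| `sxc.design` | job manifest enumeration, balanced disjoint train/validation/test splits |
| `sxc.models` | Tanimoto kernel, MCC/BA/F1, log-/hinge-loss tie-breaking, random grid search |
| `sxc.shapley` | brute-force oracle, exact SVM (restricted-kernel game) and RF (interventional game) engines |
| `sxc.aggregation` | prediction patterns, cumulative Shapley values, f_cs, PCC, FC patterns, top-k intersections |
| `sxc.mapping` | projection of present-feature values onto atoms with tri-level color bins |
| `sxc.pipeline` | resumable, fully seeded end-to-end orchestration |

## CLI

```bash
sxc run --config cfg.yaml --out runs/demo   # full pipeline (resumable)
sxc run --out runs/demo                     # desk-scale defaults
sxc generate --out data/pair --n-features 256 --n-per-class 200
sxc report --run-dir runs/demo              # print summary.json
sxc explain --run-dir runs/demo --job-id A-vs-B_size256_trial0_RF
```

The YAML config mirrors `sxc.pipeline.PipelineConfig` fields (master seed,
generator probabilities, size schedule, grids, explanation budgets).  A run
directory contains `manifest.csv`, per-job results and explanation matrices,
`metrics.csv`, `patterns.csv` + `pattern_table.csv`, `fcs.csv`, `pcc.csv`,
`fc_patterns.csv`, `feature_cumulative.csv`, `intersections.json`,
`atom_mapping.json` and `summary.json`.  Re-running an interrupted run
resumes from the stored job artifacts and yields byte-identical outputs.

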