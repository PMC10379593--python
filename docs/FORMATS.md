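# File formats

## Annotation CSV

One row per annotated image, UTF-8, header required, exactly these columns:

```
case_id,image_id,annotator,pathology,angular,calcification,distortion,indistinct,margin,micro_lobulation,orientation,posterior,shape,speculation
```

`pathology` is `benign` or `malignant` (biopsy ground truth, identical
across readers of an image). Characteristic values are free categorical
strings; the generator's default alphabet is `present`/`absent`. Unknown
columns are rejected; malformed rows are reported with their line number.

## Triple TSV

Three tab-separated columns `head<TAB>relation<TAB>tail`, one triple per
line, no header — the de-facto knowledge-graph-benchmark dialect. Reader
and writer preserve order; characteristic tails are namespaced
`relation=value`.

## Model checkpoint (`.npz`)

Single-file container of named arrays, `schema_version` 1:
`entity_embeddings` (|E|×d_e), `relation_embeddings` (|R|×d_r), `core`
(d_e×d_r×d_e), `entities` and `relations` (string vocabularies in index
order), `config_json` (training-config echo).

## Results JSON

Written by `run_experiment` / `birads-tensor evaluate`: `config` echo,
`n_cases`, `n_images`, `arms.{junior,senior,fused}` with confusion counts,
accuracy/precision/sensitivity/specificity/F1, `auc` and `auc_ci`,
`delong.{a}_vs_{b}` with both AUCs, z and p, and optional
`baselines.{knn,svm}`. Keys are sorted and floats written verbatim, so
identical seeds produce byte-identical files.

## YAML run configs

Every CLI subcommand takes `--config`; see `birads-tensor <cmd> --help`
for its required keys. A frozen copy of the effective config is written
beside each output file (`<output>.config.yaml`).
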