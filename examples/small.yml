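schema_version: 1
output_dir: runs/small
phantom:
  n_subjects: 3
  master_seed: 7
  n_per_bundle: 120
  n_per_artefact: 30
  n_background: 250
clustering:
  k_schedule: [30, 60, 120]
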