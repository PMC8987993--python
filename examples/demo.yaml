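# Demo pipeline config: synthetic 500-participant training population and
# an HC/MSA/PD application cohort sized like a small clinical study.
# Run with:  padkit run --config examples/demo.yaml
output_dir: padkit_demo_run
modalities: [GM, WM]
train_n: 500
clinical_groups:
  HC:  {n: 34, pad_shift: 0.0}
  MSA: {n: 23, pad_shift: 9.0}
  PD:  {n: 33, pad_shift: 1.0}
cv_k: 0            # set to 10 for full cross-validated performance reporting
covariates: [age, sex, education]
clinical_scores: [UPDRS_total, UPDRS_III, MoCA]
delta_threshold: 0.3
top_k: 20
exclude_lowest_counts: {MSA: 2, PD: 3, HC: 2}
reference_group: HC
seeds:
  simulate: 1
  train: 2
  cv: 3
  normative: 4
  contribution: 5
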