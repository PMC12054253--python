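# Full-scale defaults: genome-wide library profile, calibration target 2,000,
# non-responder background 0.25, Perseus-style imputation 0.3/1.8,
# 250 randomizations, volcano 0.5/2/0.05.
seed: 1
output_dir: poscreen_run
emit_fastq: false
library:
  profile: gecko_v2_default
screen:
  n_cells: 2000000
  read_depth: 10000000
  moi: 0.3
  non_responder_fraction: 0.25
  kill_prob: 1.0
  n_truth_genes: 10
filter:
  target_count: 2000
  min_occurrences_combined: 5
  min_datasets: 3
  variant: methods
  pseudocount: 0.5
stats:
  impute_width: 0.3
  impute_downshift: 1.8
  n_randomizations: 250
  fdr: 0.05
  volcano_fc_low: 0.5
  volcano_fc_high: 2.0
  volcano_alpha: 0.05
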