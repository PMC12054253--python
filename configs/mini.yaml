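# Desk-scale run on the scaled-down library profile: finishes in seconds,
# exercises every stage including the FASTQ round trip.
seed: 1
output_dir: poscreen_mini_run
emit_fastq: true
library:
  profile: mini
screen:
  n_cells: 200000
  read_depth: 100000
filter:
  target_count: 200
stats:
  proteomics:
    n_features: 500
    n_affected: 25
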