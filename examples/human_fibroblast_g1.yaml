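# Non-cycling human fibroblast irradiated in G1 (delayed plating).
parameters: {}          # best-fit defaults

phenotype:
  name: human_fibroblast
  genome_gbp: 6.1
  n_chromosomes: 46

scenario:
  phase: G1
  dose: 2.0             # used by predict-repair
  doses: "0:10:0.05"    # used by dose-response commands
  assay_time_h: .inf
  cycling: false
  plating: delayed
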