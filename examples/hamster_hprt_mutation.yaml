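# Hprt-style mutation assay in a hamster-like line (CHO cells have a
# defective G1 checkpoint).  gene_bp and b_max_bp are experiment inputs:
# the values below are user-supplied assay placeholders, not model
# constants — replace them with the target gene's own figures.
parameters: {}

phenotype:
  name: hamster
  genome_gbp: 4.8
  n_chromosomes: 21
  g1_checkpoint_competent: false

scenario:
  phase: G1
  doses: "0:10:0.5"
  assay_time_h: .inf

mutation_assay:
  gene_bp: 34000        # user-supplied
  b_max_bp: 5800000     # user-supplied
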