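# End-to-end run on a simulated compositional-attraction data set:
# codon-mode simulation -> curation -> degenerate recoding -> NDCH2
# inference (2 replicates) -> ASDSF/marginal-likelihood convergence check
# -> consensus with named-split support -> posterior-predictive X² test.
output_dir: runs/attraction_ndch2
analysis_mode: degenerate
model_mode: ndch2
replicates: 2
n_iterations: 10000
sample_interval: 10
burnin_fraction: 0.5
seed: 7
min_occupancy: 0.5
min_gene_length: 0
ppred_draws: 50
scenario:
  n_sites: 4998        # codon mode rounds per-gene lengths to multiples of 3
  n_genes: 4
  bias_strength: 0.8
  dropout: 0.1
named_splits:
  true_split: [A1, A2, B1, B2]
  attraction_split: [A1, A2, C1, C2]
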