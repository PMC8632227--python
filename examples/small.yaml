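# Small simulated study used in the README worked example.
seed: 5
n_chromosomes: 2
chrom_length: 300000
n_genes: 60
panel_size: 300
f2_size: 300
n_recessive_fine: 60
causal:
  chrom: chr2
  pos: 220000
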