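# Demo pipeline configuration: synthetic holobiont data, all stages.
seed: 7
stages:
  synth: true
  crispr: true
  provirus: true
  enrich: true
  genes: true
  betadiv: true
  network: true
synth:
  n_viruses: 8
  n_host_contigs: 6
  virus_len_range: [4000, 6000]
  host_len_range: [15000, 20000]
crispr:
  max_edits: 2
  min_spacer_len: 20
provirus:
  min_flank: 500
betadiv:
  n_perm: 499
network:
  mode: genes_as_nodes
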