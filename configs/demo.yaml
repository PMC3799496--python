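# Demo run: a small synthetic study exercising every pipeline stage.
seed: 7
outdir: clipsplice_demo
simulation:
  n_genes: 60
differential:
  n_permutations: 200
max_dist: 150
map_window: 300
map_bin: 5
map_condition: OE
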