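# Demo: fully synthetic study, every stage, one seed.
out_dir: scratch/demo_run
seed: 7
simulate: true
n_genes: 300
de_alpha: 0.05
kme_threshold: 0.65
power: auto
min_module_size: 20
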