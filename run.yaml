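# Example pipeline configuration: simulate the study at this seed and run
# every stage. Any SimConfig field can be overridden under `simulate:`.
seed: 1
outdir: scratch/run_example
stages: [atlas, differential, closure, motifs, creseq, integration]
simulate: {}
atac_fdr: 0.1
rna_fdr: 0.05
link_fdr_atac: 0.1
link_fdr_rna: 0.1
closure_window: 50000
motif_threshold: 5.0
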