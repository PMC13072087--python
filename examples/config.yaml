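# Example end-to-end configuration: 100 synthetic species with up to 500
# localities each, QC'd and analysed per region and globally.
# Run with:  nichebreadth run-all --config examples/config.yaml
outdir: nichebreadth_out
seed: 1
simulate: true
sim_params:
  n_species: 100
  locality_range: [2, 500]
  locality_distribution: loguniform
dedup_precision: 4
qc_threshold_n: 20
qc_method: auto
by_region: true
ratio_denominator: regional
pnb_index: wetdry
variance_mode: locality
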