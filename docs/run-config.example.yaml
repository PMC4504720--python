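# Example run configuration for `tetracross report --config ...`
# (also consumed by tetracross.io.load_run_config). The `sim` block
# mirrors tetracross.simulate.SimConfig; the rest are analysis flags.
sim:
  marker_positions_cM: [0.0, 6.1, 11.6]   # three markers, two adjacent intervals
  interference_shape: 2.0                 # gamma shape; 1 = no interference
  class2_fraction: 0.15                   # non-interfering (Class II) fraction
  obligate_co: null                       # null = off for FTL, on for chiasma
  n_tetrads: 5000
  n_cells: 50
  bivalent_lengths_cM: [120.0, 85.0, 95.0, 90.0, 90.0]
  viability_filter: false
  unbalanced_fraction: 0.0
  seed: 1
outdir: results/run
coc_definition: tetrad                    # or: gamete
gof_mode: pooled                          # or: paper, bootstrap
intensity_true_reduction: 0.67
intensity_noise: 0.1
intensity_n_cells: 23
chiasma_range: [6, 8]
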