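# Bundled end-to-end run on synthetic data with planted ground truth.
# Usage: remodelscan all --config configs/run_synthetic.yaml
output_dir: runs/synthetic
seed: 1
synthetic:
  n_chroms: 2
  chrom_length: 2000000   # sparse genome: elements cover ~10% of it
  n_genes: 180
  n_enhancers: 60
params:
  sigma: 20.0
  exclusion_bp: 147
  min_reads: 3
  scan_window_bp: 500
  tss_bin_bp: 5
  k_tss_clusters: 5
  k_fc_clusters: 4
  fc_min: 2.0
  synergy_fc_min: 1.5
  peak_window_bp: 1000
  peak_step_bp: 100
  peak_fdr: 0.001
  ndr_min_length: 150
  k_ndr_modes: 3
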