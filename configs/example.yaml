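# Reference profile: every printed study parameter appears as a named default.
# The simulate block generates a desk-scale synthetic panel (48 accessions,
# 3 replicates, 2 seasons, 4 population clusters) in place of the deposited
# read data.
seed: 1
outdir: runs/seed1

simulate:
  n_accessions: 48
  n_replicates: 3
  n_genes: 1500
  n_triads: 250
  n_snps: 800
  n_clusters: 4
  missing_rate: 0.02
  n_qtl: 1
  qtl_effects: [4.0]
  heritability: 0.8
  n_years: 2

expression:
  min_value: 3        # expressed iff normalized counts > 3 in all replicates
  rule: all_reps
  mode: log2p1
  low_expr_min: 1     # drop genes with < 1 raw count per sample on average

tau:
  tau_min: 0.9
  max_lines: 10
  mean_min: 10        # mean normalized counts filter
  max_min: 50         # maximum normalized counts filter
  filter_mode: max

triads:
  min_mean: 10        # eligibility: one homeolog averaging >= 10 normalized counts
  rule: nearest_ideal
  divergent_below: 0.5

network:
  power: 12
  min_module_size: 30
  merge_cut_height: 0.25
  n_top_genes: 15000  # capped at the available gene count
  fdr: 0.05

variants:
  max_missing: 0.95
  maf: 0.05
  hwe_p: 1.0e-6

eqtl:
  alpha: 0.05
  cis_window: 3000

association:
  n_pcs: 3
  sig_threshold: 5.0e-7
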