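# Annotated pipeline configuration for `enact run --config <file>`.
# Every key is optional; omitted keys take the defaults shown here.
# `enact run --out rundir` with no config runs this exact demo.

seed: 7              # global seed; all stage seeds derive from it
log_level: INFO

simulate:            # synthetic locus set standing in for the sequencing data
  n_chroms: 2
  chrom_length: 2000000
  n_genes: 60
  n_enhancers: 120   # planted enhancers (~10% strongly strand-imbalanced)
  n_peaks: 80        # decoy accessibility peaks without eRNA
  n_replicates: 3    # nascent-coverage replicates per condition
  depth: 1.0         # sequencing-depth multiplier
  n_cells_per_cluster: 60
  fragments_per_cell: 3000

inputs:              # set these to run on real fragment files instead of
  fragments: ""      # the simulated ones (5-column TSV, optionally .gz)
  labels: ""         # barcode -> cell-state TSV

enhancers:
  flank: 500         # candidate = peak midpoint +/- flank (1 kb windows)
  min_cpm: 1.0       # cpm evidence cutoff (or histone-peak intersection)
  cluster_gap: 500   # candidates closer than this merge into one cluster
  max_peak_width: 7500   # histone peaks wider than this get no dip calls
  dip_threshold: 0.5 # valley must drop below half the flanking summits
  smooth_bw: 50      # moving-average window (bp) before dip detection

quantify:
  gene_cap: 3        # per-position signal cap for gene-body counting

diffactivity:
  enhancer_cutoff: 5.0       # raw-count filter, >= in min samples
  enhancer_min_samples: 2
  enhancer_fdr: 0.1          # QL F-test reporting threshold
  gene_cutoff: 0.5           # cpm filter for genes
  gene_min_samples: 2
  gene_fdr: 0.001            # any-change LRT threshold
  kmeans_k: 6                # profile clusters for significant genes

fragqc:              # strict inequalities, per barcode
  min_fragments_in_peaks: 1000
  max_fragments_in_peaks: 100000
  min_pct_reads_in_peaks: 15.0
  max_blacklist_ratio: 0.05
  max_nucleosome_signal: 10.0
  min_tss_enrichment: 2.0

motifdev:
  B: 50              # background peak sets per motif
  effect_threshold: 1.5      # |difference of mean z| for cluster calls
  fdr: 0.0001

aggregate:
  min_fc: 0.1        # |log2FC| threshold for state-specific regions
  fdr: 0.1
  top_n: 200         # top regions per state and direction
  flank: 1000        # signal-matrix half-width (bp)
  bin_size: 25
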