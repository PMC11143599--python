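# Methods

`enact` implements the regulatory-genomics computations used to dissect
drug-induced cell-fate decisions in leukemia models from nascent
transcription (GRO-seq-style), histone ChIP, and single-cell ATAC data:
eRNA-based enhancer calling, differential nascent activity, per-cell
fragment QC with the nucleosome-signal metric, per-cell motif-deviation
activity, and chromatin-state-specific signal aggregation.  This note
describes each model, its assumptions, the parameters that matter, and
the design decisions taken where the procedure was genuinely open.

## Coordinates and containers

All coordinates are 0-based half-open (BED convention).  Strand-specific
nascent signal is held as dense per-base vectors per chromosome
(`StrandedCoverage`); minus-strand values are magnitudes — the sign seen
in browser tracks is display only.  Gene models are BED6+ rows with
absolute exon coordinates; the TSS is the strand-aware 5' end and the
promoter window is TSS −1000/+500 bp in transcribed orientation (the
promoter extent is a package choice; ±(500–2000) bp windows are all
common and nothing downstream is sensitive to the exact value at the
feature spacings used here).

## Enhancer calling from eRNA

Active enhancers produce short, bidirectional, roughly strand-balanced
nascent transcripts, whereas gene-body transcription is strongly
single-stranded.  The caller encodes this:

1. **Candidates** are `2 × flank` windows (default flank 500 bp → 1 kb)
   centered on accessibility-peak midpoints.  Windows overlapping a
   promoter, or a gene body that shows nonzero sense-strand coverage in
   the overlap, are excluded as gene transcription rather than eRNA.
   Windows that would cross a chromosome edge are dropped.
2. **Strand balance.** With per-strand window counts `p`, `m`, the
   balance ratio is `max/min` (infinite if one strand is empty).  Ratio
   ≤ 10: the locus is bidirectional and its effective count is `p + m`.
   Ratio > 10: the major strand is treated as read-through from a
   neighbouring gene (transcription extending past the annotated
   termination site) and the effective count is `2 × min` — the minor
   strand symmetrized so that effective counts stay on one scale across
   balanced and imbalanced loci.  Both strands zero excludes the
   candidate.
3. **Evidence filter.** A candidate is kept if its effective count
   reaches `min_cpm` (counts per million of the track total, default
   1.0) or its window intersects a histone-modification peak
   (H3K27ac/H3K4me1-type evidence).  A candidate with zero effective
   signal is never kept.
4. **Nucleosome-free dips.** Within histone peaks narrower than 7.5 kb,
   the per-base profile is smoothed with a 50 bp moving average and
   local minima falling below `dip_threshold` (default 0.5) times the
   smaller flanking summit are reported as dips, deepest first; dips
   closer than the smoothing window merge.  The 7.5 kb cap reflects
   where a single-valley model of a broad peak stops being meaningful.
5. **Cluster resolution.** Kept candidates whose windows lie within
   `cluster_gap` (500 bp) of each other form a cluster; the
   representative is the member with the largest base-pair overlap with
   an accessibility peak or a dip center ±100 bp, falling back to the
   member with maximum effective count; ties break to the smaller start
   coordinate.  Everything else is `merged_away`.

## Quantification and differential activity

Gene bodies are quantified on their sense strand with exon bases masked
(primary-transcript signal) and a per-position cap (default 3) that
suppresses pileup artifacts; enhancer windows are quantified with the
effective-count rule above.  Library composition is normalized with RLE
(median-of-ratios) size factors against a geometric-mean reference that
skips features containing any zero; factors are rescaled to geometric
mean 1.  Size factors replace — not rescale — the library-size offset in
the GLMs, since the median of ratios already captures depth.

**NB quasi-likelihood F-test (two groups).**  Counts are modelled as
negative binomial with log link and per-sample offsets.  Per-feature
dispersions maximize a Cox-Reid-adjusted profile likelihood on a 61-point
log-spaced grid (1e-4 … 5); features are binned by abundance (≥ 50
features per bin, up to 10 bins) and each feature's likelihood is
augmented with `prior_df / residual_df` copies of its bin's average
likelihood — weighted-likelihood empirical-Bayes shrinkage toward a mean
trend (prior_df 10).  Group means are fitted by a vectorized 1-D Newton
solve of the NB score equation per group.  The test statistic is the
deviance drop of the contrast divided by a moderated quasi-dispersion:
residual deviance / residual df, shrunk toward a common value by
moment-matching a scaled-F prior on the log scale (trigamma inversion);
the reference distribution is F(1, residual df + prior df).  An
unmoderated F on 4 residual df is poorly calibrated at 3 vs 3; the
moderated statistic's operating characteristics (null type-I error and
KS uniformity at μ=100, dispersion 0.1; recall of planted 4-fold changes
at FDR < 0.1) are asserted in the acceptance suite.  All-zero features
are reported with p = 1 by convention.

**Any-change LRT (≥ 2 conditions).**  The per-condition-means model is
compared with the intercept model by likelihood ratio on the same shrunk
dispersions, with p from χ² on (levels − 1) df; genes significant at
FDR < 0.001 are clustered with k-means (k = 6, k-means++ with 25
restarts, fixed seed) on row-standardized log1p-cpm profiles, labels
renumbered by descending cluster size.  The χ² reference is mildly
liberal at 2 samples per condition; the measured null rate stays within
a binomial interval of the nominal 5% in the test suite.

Multiplicity is controlled everywhere with Benjamini-Hochberg step-up
q-values (authored, monotone, order-preserving; checked exactly against
a brute-force step-up and an independent library implementation).

## Single-cell fragment QC

Per barcode, with duplicate multiplicities counted throughout:

* **Nucleosome signal** = fragments of 147–294 bp (mononucleosome) /
  fragments < 147 bp (nucleosome-free).  Cells in a condensed,
  mitotic-like chromatin state shift mass into the mononucleosomal mode
  and show elevated values.  If the denominator is empty the value is
  +∞ (a fully condensed profile, which deliberately fails the upper QC
  bound); with both bins empty it is undefined (NaN, fails QC).  A
  `chrom` argument can restrict the computation to one chromosome for
  fidelity with workflows that use chr1 only; the toy genome computes
  genome-wide by default.
* **In-peak fraction**: a fragment counts if either Tn5 insertion (start
  or end − 1) lies in a peak.
* **Blacklist ratio**: fragments overlapping a blacklist region / total.
* **TSS enrichment**: mean insertion density over the central 101 bp of
  all TSS ± 2 kb windows divided by the mean density over the two
  outermost 100 bp flanks.  This is a simplified, fully documented
  contract for a quantity whose reference implementations differ in
  smoothing details.

The default filter keeps barcodes with in-peak fragments in (1000,
100000), in-peak percentage > 15, blacklist ratio < 0.05, nucleosome
signal < 10 and TSS enrichment > 2 — all strict inequalities.  The
stricter multiome-style variant (in-peak percentage > 50) is reachable
through the same threshold table.

## Motif-deviation activity

From QC-passed cells, a peak × cell matrix counts insertions per merged
peak (peaks < 10 bp discarded first; peaks detected in ≤ 1% of cells
dropped afterwards).  For motif *m* with peak set *S* and cell *c*:

    expected = (Σ_S peak totals / grand total) × cell-c total
    raw      = (observed − expected) / expected

Raw deviations are standardized against `B` (default 50) background
peak sets that match each motif peak on GC content and mean
accessibility: peaks are binned on a quantile grid of (GC, log1p mean
access); the requested 10 × 10 grid is coarsened so that bins average at
least 8 peaks — on toy-scale peak sets a full decile grid would make
motif peaks match mostly themselves and collapse the z-scores.  The
z-score is (raw − background mean)/background sd.  Cells with no counts
get NaN.  Raw deviations are invariant to globally doubling counts, and
the aggregate-proportional cell has raw deviation 0 by construction.

Cluster-specific motifs: Wilcoxon rank-sum of z-scores (cluster vs
rest), effect = difference of mean z reported in the fold-change slot —
deviation z-scores can be negative, so a literal fold change is
ill-defined, but the threshold magnitude (1.5) is kept; significance
requires |effect| ≥ 1.5 and BH q < 1e-4.  Known-motif enrichment in a
region set uses Fisher's exact test against a background that excludes
the targets, with a Haldane 0.5 correction of the odds ratio whenever a
table cell is empty.

## Chromatin-state-specific aggregation

Per-cell region counts are depth-normalized to 10⁴ per cell and log1p
transformed; each region is tested per state (Wilcoxon, state vs rest)
with log2FC computed from depth-normalized means with a +1 pseudocount.
Significance requires |log2FC| ≥ 0.1 and BH q < 0.1 over all region ×
state tests; the top 200 per state and direction by |log2FC| are
flagged for visualization.  Pseudobulk tracks sum insertion coverage
over a state's cells.  Signal matrices average per-base signal in 25 bp
bins over center ± 1000 bp (80 bins; ± 2000 bp → 160 bins for TF ChIP
profiles); the region center sits on the boundary between the middle
bins, and group-wise column means give the summary histograms.

Note a structural property of the state test: with BH at q < 0.1, the
probability of at least one false call across permuted (exchangeable)
labels equals the Simes level ≈ 0.10 under independence, so roughly one
permutation in ten yields a spurious call even though the FDR is
controlled.  The permutation experiment in the acceptance suite
measures exactly this.

## Synthetic data: what it emulates, what it does not

The generator plants ground truth on a toy genome (defaults: 2
chromosomes × 2 Mb, 60 genes, 120 enhancers, 80 decoy accessibility
peaks; everything seeded).  Features are laid out with ≥ 2.6 kb gaps so
enhancers are intergenic (≥ 2 kb from genes) and neighbouring 1 kb
candidate windows never touch — the caller's cluster-resolution path is
exercised by dedicated unit fixtures instead.  Emulated structure:

* genes transcribe on their sense strand at log-uniform per-bp rates;
  enhancers emit 150–400 expected eRNA counts in a ± 300 bp window,
  split ~50/50 across strands (90%) or ≥ 92/8 (10%, to trip the
  tenfold rule); background Poisson noise at 1e-4 per bp per strand;
* 30% of genes and enhancers carry planted 2–4× condition fold changes;
  per-feature rates are Gamma-mixed (dispersion 0.1) so region counts
  across replicates are negative binomial, matching the test's model;
* histone peaks (1–7 kb, clipped to stay clear of neighbours) cover 60%
  of enhancers with two Gaussian summits flanking a valley at 20% of
  summit height — a nucleosome-free dip at the enhancer center;
* fragments per cell follow a length mixture of N(75, 25) truncated to
  [10, 146] and N(200, 30) truncated to [147, 294], mixed by each
  cell's mononucleosome fraction; three cell states are planted:
  baseline (0.3), a motif-active state (0.3, with 2× sampling weight on
  the active motif's peaks), and a condensed state (0.8).  60% of
  fragments land in peaks, 15% near TSSs, the rest uniformly; blacklist
  regions sit on down-weighted decoy peaks.

Poisson sampling is done at base level, not read level: there are no
reads, mappability structure, GC-dependent coverage bias, doublets, or
batch effects, and cells within a state are exchangeable.  Passing
tests therefore demonstrate correctness of the computations and their
operating characteristics under the stated generative model — not
robustness to alignment artifacts or biological heterogeneity beyond
that model.

## Numerical choices

Newton solves for NB group means are clipped to ±5 per step and
converge at 1e-10; dispersions are floored at 1e-6 and quasi-dispersions
at 1e-8; empty-strand balance ratios are +∞; empty-bin QC metrics are
NaN and fail the filter; background-sd floors at 1e-12 guard z-scores;
ties in cluster resolution and k-means relabeling break
deterministically (smaller coordinate / stable order).  Every stochastic
step takes an explicit seed, and the pipeline writes a manifest of
SHA-256 checksums so reruns are verifiably byte-identical.

## Problem sizes

The shipped defaults — 2 × 2 Mb genome, 6 nascent samples, 180 cells ×
3000 fragments, 2000-feature statistical simulations, 100-permutation
null experiments — were chosen so the full demo pipeline and the entire
acceptance computation each complete in minutes on a single CPU while
keeping every Monte-Carlo interval tight enough to be meaningful.

## Known limitations

* The QL F-test is validated by operating characteristics, not by
  bit-agreement with any particular published implementation; numbers
  will differ in the third decimal from other QL implementations.
* The dip detector models one valley scale (the smoothing bandwidth);
  nested or very asymmetric valleys report the deepest minimum per
  window only.
* TSS enrichment uses a fixed-window contract rather than a smoothed
  profile; absolute values are not comparable to other toolkits, though
  the QC threshold semantics are.
* `motif_enrichment` is a known-motif membership test; de novo motif
  discovery and PWM scanning are out of scope, with motif sites supplied
  as intervals.
* Cell-state labels are inputs (or synthetic); clustering/embedding of
  cells is out of scope.
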