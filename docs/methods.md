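# Methods

## Problem and model

Large hypomethylated blocks (HMBs) — contiguous regions, tens of kilobases to
megabases long, that lose DNA methylation in tumors — cover a large fraction
of the colon-cancer genome, and their edges are unusually sharp. `hmblocks`
asks what distinguishes the genome and epigenome at those edges. The unit of
analysis is the **boundary region**: a fixed 6-kb window per block edge, built
as 5 kb outside the block plus 1 kb inside (the 1 kb absorbs imprecision in
the reported block coordinate). Boundary regions are compared against three
control classes of the same length — random windows *inside* blocks, random
windows *outside* blocks, and gene *promoters* (5 kb upstream + 1 kb
downstream of a TSS, strand-aware) — under three kinds of statistics:

1. **Sequence**: each region becomes a count vector of putative transcription
   factor binding sites (one PWM per motif, log-odds scan with exact null
   p-values, threshold 1e-4, both strands, overlapping hits all counted) plus
   the fraction of the region covered by CpG islands. A random forest
   discriminates boundary regions from a control class; per-feature
   importance is mean decrease accuracy (MDA): the average drop in a tree's
   out-of-bag accuracy when that feature's values are permuted. Per-motif
   enrichment uses Fisher's exact test on presence/absence, with the sample
   odds ratio ad/bc and the calling rule OR > 2 (enriched) / OR < 0.5
   (depleted). Top-ranked, enrichment-filtered motifs are tested for
   chromatin-modification-enzyme (CME) involvement — a motif counts as
   CME-linked when its TF gene is a CME or interacts with one — against the
   remaining motifs, at k = 20, 25, 40, 50.
2. **Positional**: hit frequencies of discriminating motifs in 100-bp windows
   across the 6-kb region (right-side boundaries mirrored so window 0 is
   always the outermost end), summarized by the Z-score of the most extreme
   window against the mean and population SD over the 60 windows.
3. **Chromatin**: ChIP tracks (20-bp bins) normalized as
   log((t + 0.5)/(i + 0.5)) (natural log) and averaged into boundary-aligned
   metaprofiles over ±20 kb; region-set comparisons by two-sided Mann-Whitney
   rank-sum (exact enumeration for untied samples up to 50 per group, normal
   approximation with tie/continuity correction above); CTCF-site overlap
   frequency per region class and CTCF-stratified signal comparison; Hi-C
   intra-block interaction strength (sum of contacts over distinct fully
   contained 40-kb bin pairs divided by the bin count, diagonal excluded)
   against length-matched random regions; and TAD-boundary proximity (minimum
   distance from each TAD edge to any block edge) against random blocks.

## Classifier details

Unpruned CART trees, `m` features sampled per split (default n/3, tunable by
out-of-bag error over a grid, ties toward smaller m), majority vote.
Bootstrap bookkeeping is explicit so OOB error and MDA are computed exactly
per tree. Evaluation uses a stratified random 70–30 train/test split.
Sensitivity, specificity and F-measure are quoted at the threshold over the
held-out vote fractions that maximizes F — an optimistic choice by
construction, which the report logs; AUC is the trapezoidal area under the
ROC of vote fractions and equals the Mann-Whitney relation on the same
predictions. An SVM (RBF, 10-fold CV pooled decision values) replicates the
task as a robustness check. Default tree count is 500 for the library; the
bundled experiments use 100–200 trees, which is past the point where AUC and
the importance ranking stabilize at the problem sizes below.

## Synthetic study conditions

The generator produces every input with the structure the analysis assumes;
its defaults are the study conditions the recovery experiments run under:

* 2 chromosomes × 1.6 Mb, i.i.d. uniform-GC sequence (GC configurable);
* 50 blocks, lognormal lengths with log-sd 1.609 so the mean/median ratio
  (~3.6) matches the heavy tail of real block catalogs; the log-median
  (12 kb) is scaled to desk size. Placement enforces a 6-kb chromosome
  margin (so no boundary is clipped) and a 12-kb inter-block gap (so
  boundary regions never collide); lengths above chrom/10 are redrawn;
* 30 PWMs of width 8–12 (0.9-dominant columns), half boundary-enriched:
  planted instances sampled from the PWM, written into the sequence at
  Poisson(4.0) extra occurrences per boundary region with positions
  Gaussian-peaked (sd 300 b) at the block edge, over a genome-wide
  background of Poisson(0.5) per 6 kb for every motif;
* a promoter-like ChIP mark with Poisson peaks (height 20 over background
  5, sd 600 b) centered 500 b *outside* each edge, plus a flat control
  mark, both with matched Poisson input tracks;
* symmetric exponential-noise Hi-C matrices (40-kb bins) with +15 added to
  every within-block bin pair; TADs = blocks with 5-kb Gaussian edge jitter;
* CTCF sites on 30 % of boundaries over a 0.1-per-6-kb background; CpG
  islands on 30 % of block edges; 40 TSS placed clear of blocks and
  boundaries; a TF-interaction map wired to CMEs with probability 0.6 for
  planted motifs versus 0.2 otherwise.

All draws run through named substreams of a single seed, so a bundle is
reproducible byte for byte. The **exchangeable null** (`SimConfig.null`)
equalizes the planting rates, removes the Hi-C lift, places TADs at random,
and drops the CTCF and CpG boundary excess — under it every association
statistic is calibrated (classifier AUC ≈ 0.5, Hi-C/TAD p-values ≈ uniform).
The **3D-structure profile** (`SimConfig.chromatin`) uses 30 larger blocks
(log-median 200 kb, log-sd 0.5) on 2 × 8 Mb so most blocks span several
40-kb Hi-C bins; at the default desk scale most blocks are smaller than one
bin, which mirrors the real analysis's rule of excluding sub-bin blocks but
leaves too few for a powered comparison.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: realistic sequence composition (CpG islands are
annotation only and do not alter GC), dinucleotide structure, overlapping or
nested blocks, read-level noise, coupling between CTCF presence and ChIP
peak height, and inter-chromosomal Hi-C contacts.

## Numerical choices

* Coordinates are 0-based half-open everywhere; boundary regions clipped by
  a chromosome end are dropped, not truncated, so feature vectors always
  cover exactly 6,000 b.
* PWM columns get a 1e-3 pseudocount before log-odds; scores are discretized
  at 1e-3 bits for the exact dynamic-programming null distribution (the
  attained p-value at the threshold is reported, windows containing N never
  reach it).
* Fisher tables with a zero cell use the Haldane 0.5 correction for the
  odds ratio (flagged); p-values are always computed on the raw counts. A
  Benjamini-Hochberg column is emitted for transparency, but the OR
  thresholds — not adjusted p — do the filtering.
* Control sampling is rejection sampling over the eligible space with a
  10×n attempt budget; the pipeline accepts a reported shortfall (lognormal
  block-mass fluctuation can legitimately shrink the eligible space) while
  direct library calls treat it as an error.
* GC matching bins region GC at 2 % and subsamples candidates per bin;
  shortfalls are reported per bin, never fatal.
* Z-score ties for the extreme window break toward the window nearest the
  block edge; zero SD is reported as z = 0 with a flag.
* Metaprofile anchors are the block-edge positions; right-side anchors are
  mirrored so negative offsets always mean "outside the block".
* The boundary-vs-outside signal comparison uses the full 6-kb region sets
  rather than separate 3-kb windows; both the metaprofile span (20 kb) and
  the comparison sets are arguments, so other windows are one call away.

## Known limitations

* The F-optimal operating point is chosen on the held-out split, which
  inflates sensitivity/specificity slightly; AUC is unaffected.
* MDA is computed per tree over OOB rows with a single permutation per
  feature; at very small OOB sizes individual importances are noisy (the
  rank order of planted vs background motifs is what the tests pin down).
* With candidate pools smaller than the case set, GC matching cannot reach
  equinumerosity and reports the shortfall instead.
* Hi-C inputs are taken as already normalized; no balancing is applied.
* The TAD-proximity control re-places blocks uniformly at random, which
  ignores any real clustering of block lengths along the chromosome.
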