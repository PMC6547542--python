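# Methods

## Scope and model

`tfpair` analyses the comparative genomics of two transcription factors that
recognise the same DNA element, profiled by ChIP-seq over a shared peak
universe in a wild type and in mutants where the first factor cannot bind
chromatin. All quantitative rules are fold-change rules on pseudocounted,
depth-normalized tag counts; no parametric test is attached to the occupancy
calls, mirroring how such peak-class figures are typically produced. The
package also carries the two expression stages that complete the analysis —
bulk staged RNA profiles grouped by the direction of mutant response, and a
simplified single-cell trajectory comparison — plus a generator that plants
every structure the stages must recover.

## Coordinates, intervals, annotation

All coordinates are 0-based half-open, the native BED convention, so file
round-trips never shift positions. "Promoter" is defined as the symmetric
window ±`promoter_window` (default 1,000 bp) around a TSS, applied regardless
of strand; everything else is distal. `min_overlap` for peak intersection
defaults to 1 bp — the loosest reading of "overlapping" — and the
high-confidence filter keeps a ChIP peak iff it overlaps at least one
accessible-chromatin interval by that much. Interval queries run on interval
trees; the test suite checks them against quadratic all-pairs scans.

## Occupancy comparison

Tag-count columns are scaled to a common total (`norm_target`, default 1e7 —
an arbitrary constant, only ratios matter downstream), replicate columns are
averaged after normalization, and a pseudocount (default 1 on the normalized
scale) guards ratios near zero. The classifier labels a peak factor-specific
when the pseudocounted ratio favouring that factor is **equal to or more
than** the fold threshold (default 2); the inclusive rule is used everywhere a
fold threshold appears (classification, de-novo detection, differential
accessibility, differential expression) so boundary cases are handled one way
throughout. The de-novo detector applies the same rule to the second factor's
mutant-vs-wild-type contrast, restricted to the first factor's specific peaks.
Accessibility correlation uses Pearson on log2(normalized + 1); the transform
is a package choice, stated here because the result depends on it.

## Motif analysis

PWMs are probability matrices scored as log2 odds against a background
composition (default uniform). The default hit threshold is 80% of a matrix's
maximum achievable score — stringent enough that, for the sharp bundled
GC-box matrix (consensus GGGGCGGGGC, 0.97 on the consensus base), only exact
consensus matches pass. Multiplicity per peak counts non-overlapping hits
chosen greedily left to right across both strands; greedy selection is
deterministic and matches how tandem motif arrays are usually counted. Count
histograms are capped at "≥ 9" by default. Enrichment between peak classes is
presence/absence (≥ 1 hit) in a 2×2 Fisher exact test, odds ratios with a
Haldane 0.5 correction when a cell is zero, BH correction across motifs. The
bundled GC-box matrix is synthetic — a stand-in for an Sp-family motif model,
used by the simulator and tests; real analyses should supply their own
matrices (tabular or JASPAR count format).

## Expression grouping

Differential genes are selected by replicate-mean fold change alone (≥ 2 by
default, after flooring means at `min_expr` = 1 expression unit), with no
significance test — the analysis this package reproduces defines
"differentially regulated" by fold. "Covariance analysis" is implemented as
agglomerative clustering of row Z-scores (population SD; constant rows map to
zero) with correlation distance and average linkage, cut at K (default 13).
Rows with zero variance are assigned correlation 0 (distance 1) to everything.
The 8-way directional map is fixed as: 1 both-up, 2 A-up only, 3 B-up only,
4 A-up/B-down, 5 A-down/B-up, 6 B-down only, 7 A-down only, 8 both-down —
the constraints that matter are that 1/8 are the shared-direction groups and
4/5 the reciprocal ones; the remaining order is a documented convention.
Target genes are those with a peak within `max_distance` of the TSS (default:
the promoter window), each peak may serve several genes.

## Single-cell stage

Cells are filtered, scaled to a common total, log1p-transformed; every
downstream decision (k-means clustering, centroid tree, pseudotime) runs in
PCA space with full SVD and a fixed seed, so results are deterministic and
oracle-checkable; nonlinear embeddings are display-only by design. Pseudotime
is the tree distance from the root centroid to each cell's projection onto its
nearest edge of the minimum spanning tree over cluster centroids; branch
points are tree nodes of degree ≥ 3. The root cluster must be supplied to
`pseudotime_order` (no automatic inference); the pipeline convenience layer
picks the cluster with the lowest mean total expression, which in the
simulated lineages is the earliest population. Markers are ranked by log2 fold
change (cluster vs rest, pseudocount 1) with two-sided rank-sum p and BH q.
In the genotype comparison, a cluster is genotype-specific when its best
mean-log-expression Pearson correlation against all clusters of the other
genotype falls below the cutoff (default 0.9); matched clusters (best
correlation ≥ cutoff) get per-gene rank-sum differential tables. The
no-1-1-matching rule is deliberate: cluster boundaries shift between
genotypes, and requiring a bijection would mislabel boundary shifts as
genotype-specific populations.

## Synthetic data: what it emulates, what it does not

The generator's defaults define the study conditions used by the tests and the
acceptance script; they were chosen once, from the structure of the emulated
experiments, and are not tuned per run:

* **Genome/annotation** — 2 chromosomes × 1 Mb, 200 genes on a 5 kb grid with
  jitter, strands 50/50; promoter windows always inside chromosome bounds.
* **Peak universe** — 1,000 shared + 400 specific per factor + 200 background
  peaks of 200 bp, half placed inside promoter windows and half distal
  (echoing an even promoter/distal distribution of the first factor),
  mutually non-overlapping. All non-background peaks are accessible, plus
  half the background.
* **Tag counts** — negative binomial with mean 50 at occupied peaks,
  background mean 5, dispersion 0.1 (variance m + 0.1 m²; Poisson at 0). The
  count model is a convention: tag-count noise models are not identifiable
  from the published figures, and NB is the field standard. The planted
  specific-site fold is 4; in binding-null genotypes factor-1 signal drops to
  the background distribution (ChIP input noise is never exactly zero) and a
  compensated fraction (0.3) of factor-1-specific sites gains factor-2 signal
  to the occupied mean. Replication: 3 ChIP replicates, 2 ATAC replicates,
  2 expression replicates per condition. ATAC and RNA duplicates follow the
  emulated experiments; ChIP replication is not stated there, and 3 is the
  smallest replication at which the planted fourfold contrast is reliably
  recoverable (≥ 0.95 per-class sensitivity/specificity) at dispersion 0.1
  with the twofold rule.
* **Sequences** — uniform background with planted consensus instances;
  promoter peaks draw multiplicity from Poisson(3), distal from Poisson(0.7)
  (multiple-motif promoters vs motif-poor distal sites); instances never
  overlap, strands 50/50, and the background is rejection-scrubbed of chance
  exact-consensus occurrences so planted counts are the true counts.
* **Expression** — log-normal: baseline log2 ~ U(3, 8), one of four stage
  patterns (flat, up-ramp, down-ramp, mid-peak; the planted clusters), a
  directional group per gene (3% in each of the 8 groups, 76% unchanged)
  realized as a ×4 (or ÷4) genotype offset at every stage, and log2-normal
  replicate noise of SD 0.1. Planting one group per gene across all stages is
  a simplification — the grouping operation itself is per-stage and is
  exercised stage by stage.
* **Single cells** — 300 cells per genotype along a linear, bifurcating
  (split at t = 0.5) or multifurcating lineage: 40 shared ramp genes, 10
  branch-specific genes per branch switching on after the split, 20
  housekeeping genes, a constitutive "Kit" gene used to emulate sorting of
  the input cells, and 10 extra-cluster genes expressed only in the
  mutant-only planted population (15% of mutant cells) when enabled; 2
  housekeeping genes are down-regulated fourfold genotype-wide in the mutant.
  Noise is gamma-Poisson with CV 0.2. With the noise parameter at 0 the
  matrices contain the exact (float) expression means rather than integer
  counts — that diagnostic mode is what makes the noiseless spectral and
  pseudotime oracles exact.

Features of real data deliberately *not* modelled: per-peak depth variation
shared across samples (real occupancy spans orders of magnitude, which raises
sample-sample correlations well above what the two-level synthetic profile
gives), fragment-length and GC effects, peak-width variation, mappability,
doublets/ambient RNA, and library-specific biases. Passing recovery tests
therefore demonstrates the correctness of the analysis logic under a
controlled noise model, not performance on raw sequencing data.

## Determinism and numerical choices

A single master seed drives every generator through fixed child streams
(`default_rng([seed, stream_code])`), so modules can be regenerated
independently and whole datasets are byte-reproducible. All orderings are
made deterministic: rank matrices break ties by peak id, marker tables by gene
id, merged peaks are sorted by coordinate, JSON is written with sorted keys.
Degenerate inputs are guarded explicitly: constant rows Z-score to zero,
zero-variance profiles get correlation 0 in clustering and a named error in
sample correlation, all-zero samples cannot be normalized, single-cluster
trajectories have empty trees and zero pseudotime everywhere.

## Problem sizes

Tests and the acceptance script run at the default desk scale: a 2,000-peak
universe, 200 genes × 5 stages × 3 genotypes × 2 replicates, and 300 cells
per genotype. These sizes keep the whole suite fast while leaving enough
statistical room for the planted-recovery margins quoted above; every
operation scales to larger inputs without modification.

## Known limitations

* Fold rules inherit the arbitrariness of their pseudocount; with very shallow
  libraries the default of 1 normalized unit can dominate small counts.
* The pseudotime model projects cells onto a centroid tree: cells lying
  before the root centroid or past a terminal centroid clamp to the segment
  ends, creating ties at the extremes of the ordering.
* Cluster matching by profile correlation assumes the shared populations
  dominate each cluster's mean profile; a cluster that mixes a shared and a
  novel population can correlate above the cutoff and go unflagged.
* The 13-cluster default for expression patterns (and k for cells) are
  conventions to be chosen by inspection; no cut-selection criterion is
  implemented.
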