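# Methods

This note documents the models, parameter choices and numerical conventions
behind `coopenh`, and what the synthetic cohorts do and do not establish.

## Coordinates and overlap

All genomic spans are 0-based half-open; BED is the on-disk dialect.
Overlap means ≥ 1 shared base and is strand-blind throughout, because
H3K27ac enrichment carries no strand information.  Gene models have one
canonical TSS (the first transcribed base: `start` on the plus strand,
`end − 1` on the minus strand).

## Consensus occupancy

Candidate regions are the merged footprint (gap 0) of all peaks from all
samples; a region's support is the number of distinct samples contributing
at least one overlapping base, and regions with support below `min_overlap`
(default 2) are dropped.  The merged footprint — not the intersection — is
reported, mirroring the default mode of the tools this procedure emulates.
Signal densities on a consensus region are the unweighted mean over member
peaks; this cohort-average density is what the super-enhancer caller scores.
Consensus is monotone in `min_overlap` (raising it never adds regions), a
property the test suite checks against a per-base counting oracle.

## Peak annotation

The peak midpoint decides the feature class with precedence
TSS > 5′UTR > 3′UTR > exon > intron > downstream > distal intergenic.
Windows: TSS ± 3 kb; downstream = 300 bp past the gene end, strand-aware.
Using the midpoint rather than the full span resolves multi-class peaks
deterministically.  The nearest gene minimises |midpoint − TSS| with ties
broken by lexicographic gene id, for reproducibility.

## Super-enhancer calling

* **TSS exclusion** removes a peak only when its *full span* lies inside
  some TSS ± 3 kb window, before stitching.  Only this pre-stitch filter is
  applied; no second promoter filter runs after stitching.
* **Stitching** merges peaks whose gaps are ≤ 12 500 bp (boundary
  inclusive); every retained peak belongs to exactly one element.
* **Scoring**: `S = Σ max(0, d_ChIP − d_input) · L` per constituent.  The
  floor is applied per constituent, not per element, so a noisy
  input-exceeds-ChIP peak cannot cancel genuine signal elsewhere in the
  element.
* **Cutoff**: signals are sorted ascending over rank, both axes min-max
  rescaled to [0, 1], and the threshold is the signal at the rank where the
  curve sits farthest below the unit-slope diagonal — the tangent point of a
  slope-1 line supporting the curve from below, i.e. the rank at which the
  curve's slope crosses 1.  Ties resolve to the largest rank, which makes
  the degenerate cases exact: an all-equal vector and a perfect linear ramp
  both yield zero supers.  Elements strictly above the threshold are SEs.
  The tangent form was chosen over a literal first-crossing of the discrete
  neighbor-difference slope because single order-statistic gaps at the
  *lower* end of a heavy-tailed signal distribution can exceed the diagonal
  slope by chance, collapsing a first-crossing threshold to the minimum;
  the tangent point uses the whole curve and is insensitive to both tails.
  The partition is invariant to rescaling all signals by any positive
  constant (tested).
* **Target mapping**: *overlapping* = gene body intersects the element;
  *proximal* = TSS within 50 kb of the nearest element boundary (a
  conventional geneMapper default; not a fitted value); *closest* = the
  single gene minimising TSS-to-element distance, ties by gene id.

## Cooperative network

A gene's count is the number of *distinct* elements linked to it by any
relation — a gene reachable from one element via two relations counts that
element once.  Cooperative ⇔ ≥ k classical enhancers (default k = 5,
exposed as a parameter); multi ⇔ 2 ≤ n < k; single otherwise.  SEs are
counted separately and never contribute to the cooperative count.
Group-specificity is class-matched (SE vs SE, ENH vs ENH) with zero-base
overlap as the sharing criterion.

## Upstream-TF inference

* **Step 1** (regulon over-representation): hypergeometric tail
  P(X ≥ k) for the overlap between the target gene list and each TF's
  regulon within the declared gene universe; BH across TFs; q < 0.1 selects
  candidates.  Membership is direction-agnostic.
* **Step 2** (motif validation): PWMs are built from count matrices with
  pseudocount 0.5 and log₂-odds against a zero-order background estimated
  from the scanned sequence.  The null score distribution is computed
  exactly by dynamic programming over per-position scores integerised at
  granularity 1e-4 bits (rounding error < 1e-3 per position); the same
  integer lattice scores the scanned windows, so every reported p-value is
  an achievable tail value with no interpolation.  Both strands are
  scanned; windows containing N are skipped.  BH for motif hits is applied
  per PWM across all scanned windows of a region set (the scanner
  convention), with q < 0.1 keeping a hit; a region is "bound" when it
  carries ≥ 1 significant hit on either strand.
* **Background regions**: one shuffled region per input region — same
  chromosome, same length, uniform over valid placements, overlapping
  neither each other, the input regions, nor supplied exclusions (the
  pipeline excludes the whole consensus peakset).  Placement is rejection
  sampling with `max_tries` 1000 per region and a loud error on failure
  rather than silent relaxation.
* **Enrichment**: per TF, Pearson χ² without continuity correction on the
  2×2 bound/unbound × RE/background table (the common default in the
  environments this emulates); BH across TFs; selected ⇔ q < 0.1 *and*
  binding difference > 0 (enrichment in the analysed regions, not
  depletion); ranking by descending binding difference.

## Closing statistics

* **Fisher** (clinical tables): two-sided by the minimum-likelihood
  criterion — the sum of hypergeometric probabilities of all
  margin-preserving tables no more probable than the observed one.  This is
  the convention that reproduces the published clinical p-values and is
  verified against full table enumeration for totals ≤ 40.
* **Wilcoxon rank-sum**: exact null enumeration for tie-free samples with
  both n ≤ 25, otherwise the normal approximation with tie and continuity
  correction.  Type-I error at nominal 0.05 is calibrated by simulation
  (500 null draws at n = 50 per arm).
* **Expression hierarchy**: per-gene mean over the group's samples; three
  pairwise Wilcoxon tests BH-adjusted as a family of three.  A gene
  reachable from several element classes is assigned by precedence
  SE > cooperative > classical (configurable), making the tested sets
  disjoint.  "Expressed" defaults to mean abundance > 0 over the group —
  the weakest defensible filter; the threshold is exposed (`min_expr`).
* **Clustering**: log₂(x+1) transform of the elements × samples consensus
  signal matrix, sample distance 1 − Pearson correlation, average linkage,
  tree cut at k = 3.  The transform/distance/linkage combination is a
  documented choice, not a fitted one; a constant sample vector is a loud
  error (correlation undefined).  The procedure class, not any particular
  patient clustering, is what the implementation claims to reproduce.

## The synthetic cohort generator

The generator emulates the *data shape* of a two-group (17 primary /
12 metastasis) H3K27ac cohort after peak calling, with planted ground truth:

* **Genome**: i.i.d. bases, default 2 × 8 Mb at GC 0.41.  Genes are placed
  at ≥ 85 kb TSS spacing so the planted structures below never interleave
  within stitching or proximal reach of a neighbouring gene's layout.
* **Super-enhancers**: 50 clusters of 3–5 peaks with 2.5–5 kb gaps starting
  4 kb downstream of a driver gene's TSS (outside the promoter exclusion,
  inside the stitching reach).  Aggregate net signal = 25 × the classical
  reference signal — SEs are defined by order-of-magnitude aggregate
  enrichment, and this separation is what "default signal separation"
  means for the recovery guarantees.
* **Cooperative genes**: 50 genes with 5–6 enhancers at ±7/21/35 kb slots —
  every pair > 12.5 kb apart edge-to-edge (never stitched together) yet all
  within the 50 kb proximal window of their gene.
* **Signal**: per-element net signal ~ LogNormal(σ = 0.10) around 1200
  arbitrary units, divided by the realised peak length (element signal is
  independent of peak width); per-sample multiplicative LogNormal noise
  σ = 0.25; constant input density 0.2.  Cohort-averaged consensus signal
  therefore has ≈ 0.11–0.13 log-sd, the regime in which the ranked-signal
  curve has a clean elbow.
* **Detection**: each element (an SE cluster counts as one unit, so a
  detecting sample always carries the full peak chain) is seen in each
  eligible sample with probability 0.8, topped up to ≥ 2 samples per
  eligible group so the `min_overlap = 2` consensus rule is exercised
  non-trivially; group-specific elements never appear in the other group.
  Cluster-specific background elements (70 per cluster) give the
  three-group sample structure its signature.
* **Motifs**: the driver TF's consensus is written into SE spans at
  1 instance/kb (Poisson), and at 0.01/kb across the rest of the genome;
  every insertion is logged.  Decoy PWMs are never planted.
* **Expression**: gene-level log₂ means of 8 / 6 / 4 for SE, cooperative
  and classical targets (σ = 1, within-gene noise σ/2), emitted as
  abundances 2^x.
* **Clinical**: binary features with
  P(aggressive | cluster 1) = 1/(1+odds), P(aggressive | cluster 2) =
  odds/(1+odds); default odds 10, odds = 1 gives independence, odds = ∞ a
  deterministic table.
* **Determinism**: one master seed; each generator draws from a child
  stream at a fixed offset, so adding a generator never perturbs the
  others.  Identical seeds give byte-identical files, and an audit
  operation re-derives the planted invariants from the emitted files alone.

What passing the recovery tests shows: the pipeline's operations compose
correctly and recover planted structure under heavy-tailed signal,
per-sample dropout and boundary jitter.  What it does not show: robustness
to the things the generator deliberately omits — read-level noise,
copy-number distortion of ChIP signal, fragment-size effects, correlated
inter-sample batch structure, realistic gene density, or 3D chromatin
contacts (target mapping is purely distance-based).  Conclusions about real
cohorts still require the usual experimental QC upstream.

## Problem sizes used by the checks

The recovery suite runs 20 seeded cohorts at the defaults above; the
acceptance script runs 10 (seeds derived from `--seed`) plus the published
clinical tables and count shares.  The Fisher-uniformity calibration of the
clinical generator at odds = 1 uses clusters of 500 samples: the two-sided
Fisher p-value is discrete and conservative, and its null distribution is
close enough to uniform for a Kolmogorov–Smirnov check (α = 0.01, 200
replicates) only at that scale — at 7/8 samples per cluster, the published
cohort's size, the p-value support is far too coarse for any uniformity
test to pass, which is a property of the statistic, not of the generator.
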