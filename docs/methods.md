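# Methods notes

This note records the modelling assumptions, numerical conventions and open
design choices behind `peakrepro`, in the spirit of a statistical software
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Interval conventions

All coordinates are 0-based half-open (BED convention). Overlap means at
least one shared base; intervals meeting end-to-start ("book-ended") do
not overlap but *are* joined by the default `gap=0` merge, matching
`bedtools merge`. This choice is a documented convention: merge-tool
defaults differ, and nothing downstream depends on it beyond consistency.
Peaks are unstranded; strand enters only through the gene model in the
annotation module.

narrowPeak column 8 (−log10 p) is converted to a probability on input and
written back with seven decimal places, so p-values round-trip to better
than 1e-6 relative error.

## Consensus regions and support

Consensus regions are the gap-0 merge of the union of all replicates'
peaks; a replicate supports a region if any of its peaks intersects it,
counted once per replicate however many of its peaks fall inside. Each
supporting replicate contributes its *minimum* member p-value to the
region. Minimum is the conservative-signal choice when one replicate has
several peaks in a region; alternatives (Fisher within replicate, mean)
would blur the replicate's best evidence with fragment artifacts.

The implementation is a sorted linear sweep; its correctness is checked
against a per-base oracle (mark covered bases per replicate, take maximal
covered runs) on a thousand random instances in the test suite.

## Strategies

* **Fisher combination** uses X² = −2 Σ ln pᵢ against χ²(2m) via
  `scipy.stats.chi2.sf`; the m=1 case returns the p-value unchanged, and
  the m=2 case is validated against the closed form e^(−X²/2)(1+X²/2) to
  1e-12 relative error. Default thresholds: weak τ_w = 1e-4 (the loose
  caller threshold — a region none of whose members beat it is noise) and
  stringency τ_s = 1e-8, the documented defaults of the multi-sample
  peak-calling tool this strategy is modelled on. Support cutoff c = 1:
  any region containing at least one peak is considered, which is what
  lets weak-but-consistent signal be rescued.
* **Rank product**: within each replicate, supported regions are ranked by
  member p-value (average ranks on ties); regions a replicate did not call
  receive the worst rank M. The significance of a rank product is
  P(RP ≤ observed) under independent uniform ranks on {1..M} — computed
  exhaustively when M^N ≤ 10⁶ and by seeded Monte-Carlo (10⁵ draws)
  otherwise. Scores are used for ranking; no multiplicity adjustment is
  applied.
* **Pairwise union**: the irreproducible-discovery-rate *framework*
  (score intersecting peak pairs per replicate pair, filter, union, merge)
  with a pluggable pairwise scorer. The default scorer is the normalized
  within-replicate rank discordance |r_A − r_B|/max(M_A, M_B) — a
  deliberate lightweight stand-in for a fitted copula mixture, sharing its
  monotone rank-consistency behaviour. Merged intervals are re-ranked by
  the best (minimum) pair score among their member peaks; how to re-rank
  after merging is genuinely under-determined, and best-pair-score is the
  choice that keeps the loosest threshold equal to "all pairwise-
  intersecting peaks".

## Pseudo-gold standard and evaluation

HC requires support ≥ ⌈2N/3⌉ — the ceiling makes "at least two thirds"
literal for N not divisible by 3 (N=5 → 4, N=9 → 6) — plus overlap with
both the pG4 and oG4 evidence tracks. AN is support 1, or support 2
missing either track. The two conditions are mutually exclusive for N ≥ 2;
disjointness is asserted anyway.

TP counts *recovered HC regions* (not matching output peaks), so recall is
bounded by 1 even when one broad output peak spans several HC regions. An
output peak overlapping both tiers counts toward TP only; peaks
overlapping neither tier are uninformative and ignored — both follow from
defining FP as noise-only hits.

PR curves are computed by an incremental sweep over the ranked list (a
score threshold always selects a prefix, ties included), with thresholds
defaulting to every distinct score; this avoids grid-granularity artifacts
in the optimal F1. The AUC is the trapezoid rule over recall-sorted points
with no extrapolation beyond the observed recall range; when the curve
collapses onto a single recall value the AUC is defined as precision ×
recall of that operating point (so a strategy that recovers the standard
perfectly at every threshold scores 1, and one that only emits noise
scores 0). A curve in which no output peak touches either tier at any
threshold is reported as an error rather than a number. Optimal-F1 ties
resolve to the strictest threshold (smallest peak set).

## Genomic annotation

Categories are assigned in the fixed priority Promoter > 5′UTR > 3′UTR >
Exon > Intron > Downstream > Distal Intergenic, with the promoter a
−1 kb/+1 kb window around the TSS (txStart on +, last transcribed base on
−). The Downstream extent is not standardised anywhere; the default is
3 kb past the transcription end, exposed as a parameter. The gene model is
read from BED12 (blocks = exons, thick region = CDS, UTRs derived by
strand), keeping the package free of annotation-database dependencies. A
peak overlapping several transcripts takes the highest-priority category
across all of them.

## Design experiments

The replicate-count experiment builds the pseudo-gold standard **once from
all N replicates** and holds it fixed while k-subsets are re-analysed;
re-deriving the standard per subset would change the measuring stick with
the measurement. Subsets are drawn uniformly without replacement within a
draw; when C(N,k) is small, iterations may repeat a subset. With k = N the
experiment reproduces the full-data evaluation exactly (a consistency
check in the tests). Standard deviations are sample SDs (ddof = 1) across
iterations.

The depth-saturation fit holds F1ₘₐₓ fixed at the full-depth optimum and
estimates only the rate k by least squares, initialised at the median of
the per-point closed-form inversions k = −ln(1 − F1/F1ₘₐₓ)/d. The SSE
surface is flat for large k (every large k predicts the ceiling
everywhere), which traps interval methods such as bounded golden-section;
a gradient descent from the closed-form initialisation does not stall
there. The required depth for a performance fraction q is −ln(1−q)/k,
undefined (and rejected) at q ≥ 1. Identifiability caveat: the rate is
well determined only if some depth points lie on the rising part of the
curve (k·d of order 1); points entirely past the knee leave k weakly
identified no matter the estimator.

Depth is modelled at the generator level (detection probability and
p-value strength as functions of depth), standing in for read-level
subsampling; the fitting code is agnostic to where the (depth, F1) points
come from.

## Synthetic data generator

The generator encodes the assumed statistical structure of multi-replicate
BG4 ChIP-Seq:

* **Toy genome** 2 × 1 Mb with a tiled gene model (3 kb, 3-exon coding
  transcripts every 6 kb, alternating strand).
* **True loci**: 300 intervals of 150–600 bp, placed in promoter windows
  with probability 0.7 (G4s concentrate at promoters) and kept ≥150 bp
  apart so jittered peaks of distinct loci never merge.
* **Affinity** aᵢ ~ log-normal(0, σ=1): the heterogeneity of per-locus
  detectability that drives replicate disagreement.
* **Detection**: a replicate at depth d (millions of mapped reads) calls
  locus i with probability 1 − e^(−c·d·aᵢ); c = ln 5 / 15 so the median
  locus is detected with probability 0.8 at 15 M reads. The functional
  form matches the saturation law fitted downstream, which makes the
  depth experiment self-consistent rather than circular: the *fit* is
  still estimated from noisy simulated F1 values.
* **Peak p-values**: 10^(−g·d·aᵢ·u) with u ~ U(0.5, 1.5) and g = 0.5,
  clipped to [1e-300, 1e-4]; no emitted peak is less significant than the
  loose caller threshold 1e-4.
* **Noise**: Poisson-placed uniform peaks, 50 per Mb per replicate, with
  p ~ U(1e-6, 1e-4) — barely significant, the way caller noise looks at a
  loose threshold.
* **Evidence tracks**: true loci carry pG4 with probability 0.9 and oG4
  with 0.75; noise positions with 0.15 and 0.10.
* **Outlier**: the 9-replicate scenario thins one replicate to 3% of its
  peaks, emulating a failed library that collapses the shared-by-all
  proportion.
* Overlapping or book-ended peaks within one replicate are merged
  (minimum p kept), as real callers emit non-overlapping peaks per sample.

The three default scenarios (5, 6, 9 replicates at 15 M reads) reproduce
the qualitative behaviour the framework is built to expose: shared-by-all
proportion falling as N grows, promoter/pG4/oG4 enrichment rising with
support, Fisher combination dominating the PR comparison, F1 gains
saturating around four replicates, and F1-vs-depth following the
saturation law. These are *structural* properties of the generator plus
method, checked as seeded majority-vote tests.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: read-level artifacts (mappability, GC bias,
duplicated fragments), spatially correlated noise, antibody-specific
biases, peak-width/signal correlation, chromatin context beyond a uniform
toy gene model, and biological condition effects. Quantities that depend
on genome scale (absolute region counts, absolute depth requirements) are
on the toy scale and smaller than published values by construction; the
package's claims on real data are about the *method*, validated here
against oracles and invariants, not about those constants.

## Problem sizes in the checked experiments

Simulated experiments in the tests and the acceptance script use the 2 Mb
toy genome with 300 true loci and ~300–340 peaks per replicate (~700–900
consensus regions), 5 subsampling iterations per replicate count, 10 seeds
for majority-vote properties, and 4 depth points for the saturation fit —
sizes chosen so the entire analysis remains a desk-scale computation while
every statistical pattern of interest is still resolvable.
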