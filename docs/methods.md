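# Methods

This note documents the models and procedures implemented in
`remodelscan`, the defaults they run under, what the synthetic generator
does and does not emulate, and the design choices made where more than
one construction was defensible.

## Coordinate conventions

All intervals are 0-based half-open; the only conversions happen at file
boundaries (`remodelscan.io`). A tag is (chrom, 5′ position, strand);
BED6 is the on-disk form (`pos5 = start` on +, `end − 1` on −).
Chromosome names are matched by exact string equality — no "chr"
aliasing.

## Nucleosome calling

Each tag is extended 3′ to 147 bp, the canonical nucleosomal wrap; the
extension midpoint (`pos5 ± 73`) is the dyad estimate. Per chromosome,
the per-bp dyad histogram is smoothed with a Gaussian kernel (σ = 20 bp,
truncated at ±4σ, evaluated on the 1-bp grid). Local maxima are
candidate calls; candidates are accepted greedily in descending smoothed
height, rejecting any within 147 bp (one footprint) of an accepted call.
Each dyad is then assigned to the nearest accepted call within ±73 bp
(ties go to the leftmost call, so the partition is deterministic), and
calls keep `read_count` (assigned dyads), `occupancy`
(`read_count × 10⁶ / library size`) and `fuzziness` (population standard
deviation of the assigned dyad coordinates; a single-read call has
fuzziness 0). Calls with fewer than `min_reads = 3` dyads are dropped.

σ, the exclusion distance and `min_reads` are exposed in the config; the
defaults reproduce canonical phasing on the synthetic arrays. Fuzziness
is mildly shrunk by the ±73 bp membership window: at a true spread of
30 bp the expectation of the truncated-normal SD is ≈ 28.4 bp (−5%),
which is why the estimator tracks planted strata within ±10% but not
exactly.

Windowed occupancy tracks tile each chromosome with non-overlapping
windows (default 500 bp; 150/300 bp give mono-/di-nucleosome scales) and
count dyads per window, normalized per million. Only the per-window
difference between states is emitted; no significance test is attached
to it, because no defensible test specification exists for that
statistic at this granularity.

## Dynamics classification

Two call sets are matched one-to-one per chromosome. A pair is eligible
when the 147-bp footprints overlap by ≥ 20 bp, i.e. |Δdyad| ≤ 127. Among
eligible matchings we take maximum cardinality and, among those, minimum
total |Δ|. Because pair costs are distances between points on a line, an
optimal matching can always be chosen non-crossing (uncrossing two pairs
never raises cost or breaks eligibility), so a dynamic program over the
two sorted lists — restricted to blocks that no eligible pair can span —
finds the exact optimum deterministically. A greedy nearest-first
matcher was considered and rejected: at legal call spacing it can strand
pairs that the optimal matching keeps (A = {0, 147}, B = {127, 274}
is a minimal counterexample), and it disagrees with the exhaustive
oracle the test suite checks against.

Matched pairs with Δ = 0 are `fixed` — exact at 1-bp resolution, which
is deliberately strict: with noisy call positions almost nothing is
recovered as fixed from re-called maps (call jitter has SD ≈ σ/√coverage
≈ 4.5 bp at coverage 20), mirroring the very small fixed fractions such
pipelines report on real data. Fraction-recovery guarantees are
therefore stated against the planted dyad maps, where the matcher
reproduces planted fractions within ±3 percentage points; on re-called
coverage-20 maps, loss and gain are still recovered within ±3 points
while planted fixed nucleosomes mostly appear as 1–10 bp shifts.

Summary fractions are reported under three denominators (union of
matched-once events, |A|, |B|) because percentage statements are
ambiguous between them.

Feature enrichment assigns each call by its dyad with precedence
promoter (±1 kb of TSS) > genic (TSS–TES) > intergenic and reports calls
per kb of each class. TSS-centered composites are strand-aware
(downstream = gene direction): occupancy mode aggregates extended-read
coverage as RPKM in 5-bp bins with a 5-bin centered moving average;
call-density mode counts call dyads per 10-bp bin per million with a
3-bin average; fuzziness mode averages call fuzziness in the same
binning. The difference matrix (state B − state A per gene per bin) is
clustered with K-means, K = 5, fixed seed, `n_init = 10`; rows are
ordered by cluster and then by distance to the centroid, and cluster ids
are canonicalized by size so runs are reproducible byte-for-byte. An
all-zero difference returns a degenerate flag rather than clustering
noise.

## NDR analysis

The promoter NDR window is the closed interval −200..+50 relative to the
TSS (251 bp), mapped strand-aware to chromosome coordinates
([TSS−200, TSS+51) on +, [TSS−50, TSS+201) on −). Occupancy is
extended-read coverage summed over the window, scaled to RPKM per state.
Association with expression uses Spearman correlation (and a two-sided
Wilcoxon rank-sum test for two-group comparisons); fewer than three
joined genes is an error, not a silent NaN.

Enhancer NDRs are maximal stretches inside an enhancer intersecting no
call footprint, kept at ≥ 150 bp — one nucleosome's worth of free DNA.
Footprints reaching in from outside still block interior positions;
reported intervals are clipped to the enhancer. Mode labeling builds
state-B occupancy profiles over ±1 kb around each NDR midpoint (50-bp
bins), clusters them with K-means (K = 3), and labels each cluster by
comparing its mean state-A and state-B profiles: a center-of-mass
displacement (B − A) beyond 25 bp is a shift (negative = toward 5′);
otherwise, a state-A center more than 2× above both the state-A flank
trough and the state-B center is eviction; anything else is ambiguous
(identical inputs in both states label everything ambiguous). The
displacement and ratio thresholds are config constants
(`NdrModeConfig`). The mapping from clusters to semantics is our stated
convention; nothing in the procedure forces the three clusters to be the
three modes, and in end-to-end runs where the enhancer set carries
promoter-like contaminants the cluster means can blur toward eviction —
mode-recovery guarantees are stated for planted enhancer loci.

## Promoter histone marks

Levels are RPKM over ±1 kb promoters
(`count × 10⁹ / (2000 × library size)`). Per mark, the threshold comes
from a cascade: a Gaussian KDE (Silverman bandwidth, 512-point grid from
0 to the 99th percentile) locates the two highest local maxima; if the
minor mode reaches ≥ 10% of the major mode's height the threshold is the
density minimum strictly between them ("valley"), otherwise the sample
is declared unimodal and a 1-D K-means (k = 2) split is used with the
midpoint of the centers as threshold. In practice the active marks are
bimodal and take the valley; H3K27me3's compact distribution takes the
fallback — matching how such marks behave in promoter-level data. A
promoter is *marked* when its level is strictly above the threshold
(ties unmarked); the state string is the sorted join of marked marks,
with a bivalent flag for H3K4me3⁺H3K27me3⁺.

Transition matrices count genes by (state in A, state in B); rows sum to
the state-A counts and the grand total to the gene universe, exactly.
Fold-change clustering keeps genes whose strongest per-mark
log2((b+c)/(a+c)) change (pseudocount c = 1 RPKM) reaches 2-fold and
K-means-clusters the FC vectors with K = 4. Gain-mode classification for
an active mark is a partition: `de_novo` (below threshold in A, above in
B), `increase_existing` (above in both, ≥ 2-fold up), `lost` (above in
A, below in B), else `unchanged`.

## Enhancer identification and states

H3K4me1 peaks: 1000-bp windows stepped 100 bp, window counts tested
against Poisson(genome-wide rate × 1000), Benjamini–Hochberg at
FDR 0.1%, significant windows merged, peaks closer than 1 kb merged, and
each merged region refined to its densest 1000-bp stretch so the
reported peak matches the element scale rather than the window spread.
Peak sets from the two states are unioned; each overlapping group keeps
only its highest-scoring member (score = reads/kb/million; ties to the
earlier start). Promoter-like peaks are removed by fitting a
two-component Gaussian mixture (EM, quantile-initialized means,
tolerance 1e-6, ≤ 500 iterations, seeded) to the per-peak H3K4me3 RPKM
(max over states) and discarding peaks above the point between the means
where the weighted component densities are equal. A fit is degenerate —
no threshold, caller may supply one manually — when the means sit closer
than half the pooled SD *or* the fitted mixture has no interior density
minimum between the means (the signature of EM splitting a unimodal
sample into overlapping halves).

State thresholds come from random background: as many non-overlapping
1-kb regions as enhancers, sampled without replacement from a 1-kb grid,
per-region RPKM computed, threshold = the smallest value among the
⌈n/10⌉ largest ("top 10%", nearest-rank ceiling — on levels 1..100 this
is exactly 91). An enhancer is `off` if H3K4me1 ≤ t, else `active` if
H3K27ac > t′, else `poised`. Note the inherent limit: an off enhancer's
level is statistically exchangeable with background regions, so at tag
level ~10% of off elements are expected above a top-decile threshold;
perfect recovery holds when on-levels are ≥ 3-fold separated and off
levels sit at the background mean, which is how the guarantee is stated
and tested.

Nearest-gene assignment minimizes |enhancer midpoint − TSS| (ties:
lexicographically smaller gene id; signed distance is strand-aware). The
synergy table keeps genes with sign(expression log2FC) =
sign(enhancer-H3K27ac log2FC), both ≥ log2(1.5) in magnitude (the
expression cutoff is config-exposed; 1.5 is our default), sorted by
descending enhancer FC with promoter-mark FCs attached, and split into
up/down sets.

## Synthetic data: what it emulates, and what it does not

The generator lays the genome out as scattered 6-kb units, each holding
one gene (TSS centered; non-overlapping ±1-kb promoters) or one 1-kb
enhancer ≥ 2 kb from every TSS. Per gene it plants the canonical
−3..−1 / NDR / +1..+13 arrangement at a 180-bp repeat (−1 at −275, NDR
center at −75, +1 at +75 in gene coordinates), plus MNase-only filler
arrays in the intergenic back stretch of each unit. Dynamics labels are
drawn with exact rounded counts from the configured fractions
(default .10/.80/.05/.05). Shifts are applied to maximal runs of
consecutive shift-labeled nucleosomes as one signed displacement drawn
uniformly from [1, 120] bp: neighbors at a 180-bp repeat cannot each
move ±120 bp independently without physically overlapping, and coherent
array sliding is also what the downstream-shift cluster patterns in this
kind of data describe. Block boundaries are compressed to keep planted
state-B dyads ≥ 175 bp apart (just above one footprint, so neighboring
calls stay resolvable); a shift squeezed back onto its own position is
relabeled fixed.

A configurable gene subset (default 30%) has its promoter NDR occupied
in state A (weight ~ U(0.7, 1)) and free in state B; the rest carry a
stable weight ~ U(0, 1) in both states. When this NDR machinery is
active the −1/+1 flanking nucleosomes are pinned fixed — they are the
strongly positioned nucleosomes, and letting them wander into the
−200..+50 window would corrupt the planted occupancy contrast.
Enhancers carry a five-nucleosome array; state B realizes one planted
NDR mode per enhancer: eviction removes the central nucleosome (213-bp
gap), shift5/shift3 slide the central and flanking nucleosomes 150 bp
toward 5′/3′ (≈ 180-bp gap, displaced center of mass).

MNase reads are Poisson(coverage × weight) per nucleosome with dyads
~ Normal(planted dyad, fuzziness) rounded, uniform strand, and the 5′
position back-computed from the 147-bp geometry; reads whose footprint
leaves the chromosome are dropped (never truncated) so the dyad model
stays exact. ChIP tags are placed uniformly within elements with counts
proportional to a level drawn from the mark's two-component mixture
(per-gene boolean states with 0.7 persistence between cell states;
enhancer H3K4me1/H3K27ac levels follow the planted active/poised/off
state at ≥ 3-fold above background) over a uniform genome-wide
background (1 tag/kb). Expression is
log2(FPKM+1) = 6 − coupling × (NDR weight) + N(0, 0.3) with coupling 1
by default; genes nearest an enhancer that switches into or out of
`active` get an extra ±2 log2-unit synergy effect with matching sign.
One named RNG stream per (module, mark, cell state) hangs off the master
seed, so adding a mark never perturbs other outputs, and identical
(config, seed) runs are byte-identical.

Not emulated: sequence content, mappability and MNase digestion bias,
PCR duplicates, paired-end fragments, replicate structure, copy-number
or chromatin-domain heterogeneity, and distance-dependent
enhancer–promoter wiring (nearest-TSS is ground truth by construction).
Passing recovery tests therefore demonstrates the correctness of the
estimators and classifiers under their own generative assumptions, not
robustness to the biases of real libraries.

## Problem sizes and numerical choices

Default study conditions: 2 chromosomes × 500 kb, 120 genes, 40
enhancers, ~2,900 planted nucleosomes, coverage 20, fuzziness 20 bp —
the conditions under which ≥ 95% dyad recovery within ±20 bp holds.
Enhancer-bearing end-to-end runs use a sparser genome (2 × 2 Mb, 180
genes, 60 enhancers) so that regulatory elements cover ~10% of the
genome: with a denser layout the background top-decile threshold lands
on element signal, which is a property of the threshold rule, not of the
implementation. Expression-coupling analyses use 1,000 genes on
2 × 4 Mb. All K-means runs use `n_init = 10` and a fixed seed; the EM
mixture uses `reg_covar = 1e-9` so point-mass components stay finite;
KDE valley search uses a 512-point grid; BH correction is applied over
all windows genome-wide. Degenerate inputs (all-zero difference
matrices, unimodal mixtures, gene-free chromosomes, empty peak sets)
return flags or typed errors rather than arbitrary numbers.

## Known limitations

* GeneTrack- and HOMER-style callers are re-implemented with stated
  parameters; the original tools' unpublished internals (and the
  upstream study's exact settings) are not reproduced, so absolute call
  counts on real data will differ even where the logic matches.
* Window-level occupancy differences carry no significance test (see
  above).
* "Fixed" at Δ = 0 exactly is not recoverable from noisy re-called maps;
  consumers who want a tolerance should treat |Δ| ≤ k as fixed
  downstream of the match table.
* The enhancer set retains H3K4me1⁺/H3K4me3⁻ promoters — the one class
  the K4me3 filter cannot remove by construction.
* The mode-labeling convention (center-of-mass displacement sign) is a
  choice; other conventions would permute the shift5/shift3 names.
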