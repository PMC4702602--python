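# Methods

## The structural model

The package is organized around the exonuclease-stop geometry of ChIP-exo.
Formaldehyde cross-links a DNA-bound protein at one or a few base positions;
lambda exonuclease then digests 5'→3' on each strand until it is blocked
~6 bp 5' of the cross-link. The 5' ends of sequenced tags therefore form a
plus-strand peak 6 bp to the genomic left of the cross-link and a
minus-strand peak 6 bp to its right: a *peak pair* with separation
2 × 6 = 12 bp whose midpoint estimates the cross-link position.

For the GATA1/TAL1 system the model is anchored at the WGATAA element. The
reference base is the 5th base of WGATAA (0-based index 4); every offset in
the package — cross-link positions, occupancy windows, composite-profile
axes — is measured from this base along the motif strand. GATA1 cross-links
at the two edges of its site, offsets −8 (major) and +8 (minor); TAL1
cross-links at −21 and −13, flanking the distal end of the composite
TG[N₇₋₈]WGATAA element. These offsets are what the simulator encodes and
what the analysis chain must recover; nothing in the calling or profiling
code knows them.

One ±1 bp ambiguity is inherent: the motif reference base could equally be
defined half a base differently ("motif midpoint" vs a specific A). The
choice of index 4 is config-exposed (`ref_index` in the scanners), and all
downstream offsets inherit it consistently, so recovered geometry is
internally exact even if an absolute comparison to another convention could
differ by 1 bp.

## Peak calling and pairing

Tag 5' ends per strand are convolved with a discrete Gaussian (σ = 5 bp,
truncated at ±4σ and renormalized, so total tag mass is preserved to
~10⁻⁴ relative error away from chromosome edges). Peaks are local maxima
taken greedily from the highest smoothed value down, discarding candidates
closer than the 10-bp exclusion zone (center-to-center) to an accepted
peak; plateaus resolve to their leftmost position. Each peak's raw count is
the tag total within ±⌊exclusion/2⌋ = ±5 bp; peaks with fewer than
`min_raw = 3` tags are dropped — the floor keeps singleton-tag noise from
flooding the pairing stage.

Pairing applies the window d = minus − plus ∈ [−5, +25] bp. The window is
deliberately oriented so that it contains the +12 bp separation the stop
geometry produces (the plus peak left of the minus peak); the opposite
literal orientation is available via the `d_min`/`d_max` arguments.
Matching is one-to-one: scanning plus peaks left to right, each takes the
eligible unmatched minus peak minimizing |d − 12|, breaking ties by larger
raw count and then smaller coordinate. Peaks are sorted internally, so the
result is invariant to input order.

## Enrichment testing

For each pair, tag counts on both strands within ±40 bp of the midpoint are
taken from the ChIP and input tracks (the ±40 bp window matches the
co-occupancy scale used throughout; it is a parameter). The fold estimate
is chip / (s·input + 1) with s the chip:input total ratio; the pseudocount
of 1 only guards the ratio against empty input windows. Significance is the
upper-tail exact binomial of the chip count out of chip + input at success
probability total_chip/(total_chip + total_input) — under the null that a
window is unenriched, its tags split between the libraries in proportion to
depth — with Benjamini–Hochberg correction across all tested pairs. Pairs
with fold > 2 and q < 0.05 are retained. The test presumes libraries of
broadly comparable depth, as in real designs; an input library orders of
magnitude shallower than the ChIP makes the null success probability
approach 1 and the test powerless, which is a degenerate design rather than
an analysis setting. The synthetic workflows therefore depth-match the input
control to the ChIP library.

## Consolidation

Locations from multiple conditions are unioned by single-linkage chaining
of midpoints with gaps ≤ 40 bp; the union coordinate is the
occupancy-weighted mean (rounded), and per-condition occupancies and
bound-in flags are retained. The union is then intersected with an external
event list (MultiGPS-style, consumed as a TSV): external locations with at
least one union location within 100 bp become final binding locations at
the external coordinate, with the supporting-pair count recorded; both
outersects are returned for reporting. No further deduplication is applied
— several close pairs may support one final location.

## Motif scanning

IUPAC scanning reports exact matches on both strands (minus-strand hits via
the reverse complement), with p-value = (product of allowed-letter
counts)/4^L. PWM scanning scores log-odds against a uniform background
(IUPAC-derived matrices are uniform over allowed letters with pseudocount
10⁻³) and computes exact p-values by dynamic programming over the score
distribution discretized at 0.01 log-odds units; window scores are binned
identically, so scanner and p-value function agree exactly, and both are
verified against full 4^L enumeration for short motifs. The default
reporting threshold is p < 10⁻³; a threshold of 1 reports every scorable
window. Locations are centered on the most significant hit within 40 bp
(ties: nearest, then lower coordinate); locations without a hit are flagged
motif-less and left in place.

The upstream-TG scan measures, on the motif strand, the number of
intervening bases between the G of a TG dinucleotide and the first base of
WGATAA (so TGN₇WGATAA → 7), recording all occurrences at distances 1–20.
The scan range is clipped at chromosome edges; a site counts as skipped
only when no distance is scannable. When one TG must be chosen per site,
the occurrence closest to the 7–8 band wins, ties toward the smaller
distance. E-box classification reads the 4 bases 5' of the chosen TG as
ZZNN and tabulates ZZ classes, NN classes within ZZ = CA, the full-E-box
(CANNTG) fraction, and the MA/BG dimorphism fraction using standard IUPAC
degeneracy classes (M = A/C, B = C/G/T).

## Composite profiles and cross-link estimation

Composite profiles accumulate strand-separated tag counts at offsets
relative to oriented anchors; minus-strand anchors contribute with offsets
negated and strands swapped, so profiles read in motif-strand orientation
(upstream left). Densities are per anchor per bp, smoothed with a centered
moving average (5 bp for exo profiles, 20 bp for the broader ChIP-seq-style
views). The profile is equivariant under reverse-complementing the whole
dataset (property-tested).

Cross-link estimation finds local maxima independently on the plus and
minus composite densities (above 10% of the profile maximum, a floor that
suppresses jitter ripple without hiding a 25%-weight minor pair), forms all
plus/minus candidate pairs within the same [−5, +25] separation window, and
selects pairs greedily by |separation − 12| then intensity (the mean of the
two maxima), one-to-one. Preferring near-12-bp separations first is what
prevents mispairing the inner peaks of two adjacent cross-links (e.g. the
TAL1 −19/−15 maxima, 4 bp apart, which would otherwise form a spurious
midpoint). Each selected pair's midpoint is a cross-link estimate; up to
`max_pairs` (default 2) are returned by descending intensity.

## Occupancy, heatmaps, clusters, expression

Occupancy is the tag count (both strands) in a factor-specific
strand-oriented window around the reference point: −25..+25 bp for GATA1,
−40..+30 bp for TAL1, both ends inclusive. "Within 40 bp" comparisons are
inclusive (≤ 40) everywhere in the package. Heatmap matrices sort anchors
descending by total occupancy or by one of the four composite-peak windows
(sense [−25,0] / [0,+25], antisense [−25,+5] / [+5,+25], strand-specific);
ties keep coordinate order, and row order is shared across linked matrices.

Homotypic clusters chain adjacent midpoints closer than 500 bp
(single-linkage, strict inequality); a chain of length ≥ 2 is a cluster at
the median member coordinate (even sizes: rounded mean of the central two),
and isolated locations are nonclusters. Each cluster or noncluster location
is assigned the gene with the nearest TSS (ties toward the lower
coordinate), and cluster vs noncluster expression changes are compared with
a two-sided Mann–Whitney U test.

## Concordance and kinetics

Exo/seq overlap uses the 40-bp midpoint rule (equivalently an 80-bp
window), counted in both directions because several exo peak pairs can
share one broad seq interval; per category, the fraction of locations with
a motif reference point within 40 bp is reported. Occupancy consistency is
the Spearman correlation of log₁₀(count + 1) in 400-bp windows around
anchor midpoints (the pseudocount of 1 is the package's choice for zero
windows). The composite exo profile around seq-only midpoints (20-bp
smoothing) reports whether its mode falls within ±10 bp of the anchors —
the signature of real but sub-threshold binding.

Differential occupancy scales per-location window counts so total tag
counts are equal across time points, then takes log₂((a + 1)/(b + 1)) for
each stated ratio (e.g. 3h/0h, 24h/3h, 24h/0h); the normalization makes the
result invariant to library-depth rescaling up to pseudocount effects.
Dispersion-modelled differential testing (edgeR-style) is intentionally not
reimplemented — the downstream clustering consumes fold changes, and
externally computed per-location statistics can be supplied in its place.
k-means (k = 6, 10 restarts, fixed seed) clusters the fold-change vectors;
clusters are ranked by mean late/early fold change and grouped 2/2/2 into
increased, unchanged and decreased, making the grouping deterministic
rather than by-inspection.

## The synthetic-data generator

`simdata` emulates the statistical structure the analysis assumes, with
ground truth for every placement:

- **Genome**: i.i.d. bases at a stated GC fraction (default 0.42,
  mammalian-like).
- **Sites**: cobound sites carry TG[Nₛ]WGATAA with s drawn from {7, 8};
  GATA1-only sites carry WGATAA with upstream TG scrubbed from the 1–12 bp
  band; TAL1-only sites carry a CAGMTG E-box with no WGATAA within 40 bp.
  Strands are equiprobable; sites are spaced ≥ 600 bp by default so that
  event detection and clustering are decoupled unless clustering is under
  test.
- **Occupancy**: lognormal(μ = 3, σ = 1) per site — a heavy tail that
  reproduces the appearance of sorted occupancy heatmaps; TAL1 occupancy at
  cobound sites shares the site strength (times a small lognormal wobble),
  which yields the positive GATA1/TAL1 occupancy correlation at cobound
  sites. Per-site tag counts are Poisson with mean proportional to
  occupancy, scaled so the site-average equals `mean_tags_per_site`.
- **Exo tags**: per molecule one cross-link is drawn by weight
  (GATA1 −8/+8 at 0.75/0.25 — the major:minor ratio is not quantified by
  the structural model, so it is a configurable default; TAL1 −21/−13 at
  0.5/0.5, with an optional third downstream offset, off by default);
  plus/minus 5' ends are placed ±6 bp of the cross-link with independent
  rounded-Gaussian jitter (sd 1 bp — sharp single-base peaks that remain
  detectable after smoothing). Minus-strand motifs mirror all offsets.
  Background is strand-independent uniform Poisson.
- **Seq tags**: 5' ends at sonication breakpoints — a fragment of
  Normal(200, 50) length overlapping the site uniformly, with the 5' end at
  the left (plus) or right (minus) fragment end — giving broad unimodal
  strand densities.
- **Annotation**: uniform TSS positions; genes nearest a cobound site draw
  expression log₂FC from N(effect, sd), others from N(0, sd).

What the generator does *not* model: read sequences or qualities, aligner
artifacts, PCR duplicates, mappability, chromatin-accessibility background
structure, or cross-link-efficiency sequence bias. Tests passing on this
generator therefore validate the geometry and statistics of the chain, not
robustness to those real-data artifacts.

## Problem sizes and numerical choices

The test and acceptance workflows use 300–400-kb genomes with 250–500
embedded sites and ~50 tags per site — sizes at which every geometric
quantity is already recovered exactly and the whole suite runs in seconds.
The full-chain recovery criterion (≥ 95% sensitivity within 20 bp, ≤ 5%
false discovery beyond 40 bp) is evaluated over sites meeting the stated
coverage condition of ≥ 50 tags; with lognormal occupancy a small tail of
sites receives an order of magnitude fewer tags than the mean, and such
sites are below any method's detection floor (they are reported, not
asserted against). Determinism: every stochastic routine takes an explicit
seed (numpy `default_rng`); k-means uses a fixed `random_state` with 10
restarts; greedy selections break ties by explicit keys (height then
coordinate; p-value then distance then coordinate), so all outputs are
bit-reproducible.

## Known limitations

- The enrichment binomial treats tags as independent; clustered duplicates
  would inflate significance (no duplicate modelling is attempted).
- The cross-link estimator assumes at most `max_pairs` well-separated
  cross-links per strand pair and a shared stop offset; heterogeneous
  offsets would bias midpoints.
- The exact-p-value DP discretizes scores at 0.01 log-odds units; motifs
  with near-degenerate column scores could alias across one bin (verified
  exact for the motifs used here by enumeration).
- `intersect_locations` scans per external location (adequate for desk
  scale; an interval-tree implementation would be preferable for
  genome-scale lists).
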