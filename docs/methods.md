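# Methods

## Scope and model

`reefnet` reconstructs a bipartite virus–bacteria interaction network from
three kinds of tabular evidence and resolves it by abundance. The model of
the system is deliberately simple: a community of bacterial species (bMAGs)
and viral populations (vMAGs) in seawater, observed through (i) chimeric
proximity-ligation reads linking viral and host DNA inside cells, (ii)
high-identity alignments of viral contigs inside host contigs (integrated
prophages), (iii) CRISPR spacers recording past infections, (iv)
mapped-read counts in two size fractions — cell-associated (>0.22 µm) and
free (<0.45 µm) — and (v) epifluorescence microscopy totals (cells/ml,
VLP/ml). Links are directed pieces of evidence about pairs; abundances are
genome copies per ml; everything downstream (VHR, network statistics,
trees) is a deterministic function of these tables and the configured
thresholds and seeds.

## Link inference

Filters are boundary-inclusive and mirror standard practice for each
evidence class:

* prophage: `percent_identity ≥ 95` and query (viral-contig) coverage
  `≥ 99%`, coverage computed as `(|qend − qstart| + 1) / query_length` so
  strand is irrelevant. Coverage is viral-side only: the question is
  whether the whole viral contig sits inside a host contig.
* CRISPR: `mismatches + gaps ≤ 2`, `coverage = 100%`, matched length
  `≥ 20 nt`.
* Hi-C: `contact_count ≥ 2` and `normalized_score ≥ 0` by default. The
  upstream deconvolution software that produced the study design's contact
  confidence is proprietary, so this filter is a transparent stand-in with
  both thresholds exposed in the config.

Dereplication is single-linkage over similarity edges (viruses: ANI ≥ 95%
and shared genes ≥ 80%; hosts: ANI ≥ 95%), with the longest genome as
representative (ties to the lexicographically smallest id). Single linkage
matches common viral-population practice and is deterministic; its known
risk (chaining) is acceptable at these strict thresholds. Merged output is
one row per (virus population, host species) with the set of evidence
types, per-type support sums and per-sample presence; re-merging merged
evidence is a fixed point.

Lifestyle: a virus observed integrated is `temperate_prophage`; an
integrase-encoding virus never observed integrated is `temperate`;
otherwise `lytic`. The coarse two-class view folds both temperate
subclasses together.

## Abundance and VHR

Relative abundance uses reads/length renormalized per sample
(RPKM-proportional); the raw read fraction is reported alongside. Scaling
multiplies viral entities by VLP/ml and bacterial entities by cells/ml,
each within its own entity class, so proportions are preserved exactly and
the scaled class sums to the microscopy total. Cell-associated viral
abundances therefore share the VLP scale; this is a per-sample common
factor, so within-sample comparisons and pair rankings are unaffected, but
cell-associated VHRs are interpretable relative to the free-particle
total rather than as absolute intracellular copy numbers.

VHR divides virus genomes/ml (each fraction) by the linked host's
genomes/ml (cell fraction) per sample. Pairs in samples where the host is
absent are emitted with undefined VHR and excluded from quartiles; a
pseudocount path (add reads before normalization) exists for users who
prefer imputation. Per-pair medians across samples feed the quartile
classification — one point per pair, matching how such data are plotted;
a per-sample alternative would multiply the point count by the number of
samples and is intentionally not the default.

Quartiles are computed on log10 VHRs (ratios span decades; linear is a
config option) with linear interpolation between order statistics. "High"
is strictly above Q3 and "low" strictly below Q1 — points on the quartile
lines are "middle" — giving five exhaustive, mutually exclusive labels:
category 1 (low cell, high free), 2 (high/high), 3 (low/low), 4 (high
cell, low free), middle. With independent quartile lines at most 25% of
pairs can exceed a line per axis, so the middle class is always sizeable
by construction.

Group comparisons run Shapiro–Wilk per group (the recorded justification
for the nonparametric route), Kruskal–Wallis, then pairwise two-sided
Wilcoxon rank-sum tests: exact null distribution for groups of ≤ 25
without ties, normal approximation with continuity correction otherwise.
Pairs with p < 0.05 are summarized as a compact letter display
(insert-and-absorb). No multiple-testing correction is applied by default;
Holm adjustment is a flag.

Rank statistics use average ranks (1 = most abundant) within samples,
medians and standard deviations (ddof = 1) across samples, and Spearman
correlation between linked virus and host median ranks.

## Network statistics

* **NODF**: for every ordered pair of rows (and of columns) with strictly
  decreasing marginal totals, the fraction of the sparser line's presences
  shared with the denser line; equal totals contribute zero; the mean over
  all row and column pairs is reported on a 0–1 scale. Verified against
  vegan's `nestednodf` in the test suite.
* **Nestedness temperature**: rows and columns are packed by descending
  totals; cell (i, j) sits at the center of its patch of the unit square;
  the isocline is the straight line `x + y = c` with area above-left equal
  to the fill; presences beyond the line and absences before it are
  unexpected; `T = 100 × Σ_unexpected d² / Σ_all d²` with `d` the signed
  diagonal distance to the line. Tied marginal totals have no canonical
  packing order, so tied lines contribute the expectation over a uniformly
  random arrangement of their block — this makes T exactly invariant to
  row/column permutations (a 4×4 checkerboard gets T = 50 under this
  rule). The score `1 − T/100` is reported so that 1 means perfectly
  nested, matching the orientation in which high published NTC values are
  read as "nested". All-ones and all-zeros matrices take T = 0 by
  convention.
* **SS null model**: permutations scatter the observed number of 1s
  uniformly over the cells (size and fill conserved);
  `p = (1 + #{null ≥ obs}) / (1 + n_permutations)`. Calibration is tested:
  when the observed matrix itself comes from the null, p-values are
  uniform (KS check at 500 replicates).
* **Barber modularity**: joint host/virus module labels maximizing
  `Q = (1/m) Σ (A_ij − k_i d_j/m) δ(g_i, g_j)` by alternating best-label
  propagation with single-node refinement, greedy module agglomeration,
  and dissolution of modules containing only one node class (they
  contribute nothing and would otherwise inflate the module count of
  structureless matrices). Best of 20 restarts (restart 0 deterministic,
  the rest seeded); the per-restart iteration cap defaults to 100.
  Normalization divides by the Q of an idealized matrix with the same
  marginals and all edges within modules; a matrix whose ideal Q is 0
  (complete bipartite) reports normalized Q = 0. On every matrix small
  enough to brute-force, the optimizer is required by test to match
  exhaustive search over all joint set partitions.

A note on module counts: splitting disconnected components always
increases Q (it only removes null-model mass), so an exact maximizer
reports at least as many modules as the network has components. Published
module counts from heuristic tools can be lower for sparse
specialist-dominated networks whose components outnumber their visual
blocks.

## Proteomic trees

Dice distance `1 − 2·AB/(AA + BB)` over summed bitscores, with directed
sums symmetrized by their mean (order-independent; the data rarely say
which search direction a published sum used), missing pairs as AB = 0
(distance 1), and clipping at 0 when raw sums exceed the bound.
Neighbor joining follows Saitou–Nei with the standard Q criterion,
lexicographic tie-breaking for determinism, and negative branch lengths
clamped to zero with the deficit moved to the sibling branch (path
lengths through the join are preserved). The last three lineages join at
an unresolved central node via the closed-form three-point solution. NJ
is exact on additive matrices; tests require path-sum errors below 1e-9
up to 8 taxa and topological agreement (Robinson–Foulds 0) with
dendropy's independent NJ.

## Synthetic communities

The generator emulates the observable layers of the study design at the
summary-table level (no sequences):

* hosts get log-normal abundance weights per sample (default µ = 0,
  σ = 1), renormalized so each sample totals a configurable cell density
  (default 9.6×10⁵ cells/ml, the median reef boundary-layer density the
  design targets); optional extra unlinked hosts with boosted weights
  emulate abundant lineages absent from the link network.
* the infection network is planted as blocks (modules) of hosts and
  viruses with either a nested staircase fill (virus *i* of a block links
  the block's first `max(1, m − i)` hosts) or a specialist fill (every
  virus one host), plus `⌈f·n_viruses⌉` generalists with one extra
  out-of-module host (the first generalist can take more, mirroring the
  single stand-out generalist real networks tend to contain).
* per-virus log10 VHRs for the two fractions are drawn from a correlated
  bivariate normal (defaults: free ~ N(1.0, 0.8), cell ~ N(0.3, 0.8),
  correlation 0.7), and viral abundances are VHR × primary-host
  abundance, so every downstream ratio has a known true value and the
  free-vs-cell VHR relationship of real data (decades of spread, strong
  positive association) is reproduced.
* evidence: Hi-C counts are Poisson with mean proportional to the pair's
  host × cell-virus co-abundance, anchored so the rarest true pair expects
  `hic_links_per_infection` contacts (default 10 — the depth at which
  detection of every true link is near-certain); prophage alignments carry
  identity `100 − |N(0, σ)|` at 100% coverage; spacer matches draw
  mismatches binomially. Decoy alignments/spacers and a false-positive
  Hi-C floor (all off by default) sit strictly below the published
  thresholds to exercise the filters.
* read counts are multinomial per sample and fraction with weight
  `abundance × genome length` (reads scale with DNA mass), which the
  length-normalizing estimator inverts — making estimator correctness a
  round trip against the generator's own weights; an `exact_reads` mode
  substitutes expected counts for exact algebraic round trips.
* microscopy totals are the true abundance sums times multiplicative
  log-normal noise.

What the generator does *not* emulate: assembly and binning artefacts,
chimeric bins, uneven genome completeness, contamination, read mapping
ambiguity, RNA viruses and vesicles inflating VLP counts, or
within-population strain structure. Passing tests therefore demonstrate
correctness of the estimators and statistics under the stated sampling
model, not robustness to upstream bioinformatic error.

## Problem sizes and determinism

Default study-scale runs use 51 linked hosts (+10 unlinked), 88 viruses,
29 planted modules, 8 generalists, 6–18 samples, 10⁶ reads per
sample/fraction, 999 SS permutations and 20 optimizer restarts; the
bundled demo and acceptance script complete in seconds on one CPU. All
randomness flows from explicit `numpy.random.Generator` seeds recorded in
the run manifest; identical config + inputs give byte-identical outputs.

## Known limitations

* The Hi-C confidence filter is a declared stand-in for a proprietary
  step; its defaults are not calibrated to any published threshold.
* Quartile classification on per-pair medians cannot reproduce published
  per-category counts whose totals exceed the number of unique pairs
  (those imply per-sample points); the per-sample path exists but is not
  the default.
* The nestedness temperature is a documented variant (straight isocline,
  squared-distance ratio, expectation over tied blocks); absolute values
  are not comparable to other NTC implementations, though orientation and
  ordering are.
* Normalized modularity of 1.0 on recovered synthetic networks reflects
  the planted block structure; real networks with cross-module links will
  score lower and their module count depends on the optimizer's exactness
  (see the module-count note above).
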