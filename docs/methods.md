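# Methods

## Distances and barcoding gaps

All distances are uncorrected p-distances with **pairwise deletion**: a
column contributes to a pair iff both characters are in {A,C,G,T}; gaps,
N and (on input) every other ambiguity code are missing data. No model
correction (JC, K2P) is offered — at the divergences involved
(≤ 0.33 substitutions/site locus-wise) the p-distance is the statistic of
record for this kind of barcoding table, and corrections would change the
gap calls only through a monotone transform. Pairs with zero comparable
sites are flagged undefined; the whole-matrix builder either raises
(naming the pairs) or, for summaries, silently drops those pairs.

Pair classes: at the species level a pair crossing two varieties of one
species is **intra**-species; the variety level is defined only inside a
multi-variety species. This matches the way published locus tables nest
their four range columns. A config-free consequence is that
`inter-species + intra-species = C(n,2)` exactly, which the tests assert.

A barcoding gap at a level requires `min(between) > max(within)`
**strictly** — touching ranges are "overlap", reading "no overlap"
conservatively. `gap_width` may be negative (overlap depth), which keeps
the monotonicity property (raising all between-group distances can never
destroy a gap) trivially testable.

## Windowed substitution rates

Windows are laid on **alignment columns**, not reference coordinates: the
profile describes the alignment the trees are built from, and the
sliding-window tools this emulates operate on alignment positions. A
reference-projected profile can be had by extracting loci first. The
partition uses fixed-width non-overlapping windows with the remainder
rule: a final fragment shorter than w/2 is merged into the previous
window, so no thin, high-variance tail window exists.

Per window and level the rate is the unweighted mean over group pairs of
Dxy (mean cross-group pairwise p-distance, pairwise deletion within the
window). With the study design there are exactly 2 groups at each level,
so the mean is the single pair value. A window is **invalid** at a level
when the average comparable-site count across cross pairs falls below
`min_valid_sites` (default w/2); invalid windows are excluded from
correlations, maxima and hypervariable calling. Pooling the mismatch and
site counts of all windows reproduces the whole-alignment Dxy exactly
(conservation under partition), which the suite checks.

Hypervariable calling selects windows whose rate is **strictly greater**
than the `threshold_quantile` (default 0.95) of valid window rates; a flat
profile therefore yields no calls rather than all windows. Selected
windows separated by at most `merge_gap` (default 1) unselected windows
merge into one region; regions are ranked by peak rate. The quantile is a
reporting device, not a significance test, and is always printed with the
calls.

## Trees and identification

Neighbor joining follows the Saitou–Nei agglomeration with two
deterministic conventions:

- among exact Q-minima the pair whose sorted leaf-representative ids are
  lexicographically smallest is joined (the representative of an internal
  node is the smallest leaf id beneath it), making output invariant to
  row order;
- negative branch lengths are clamped to zero with the deficit moved to
  the sister branch, preserving the pair's length sum;
- zero-length internal edges are collapsed: they carry no distance signal,
  and an all-zero matrix then yields the star topology instead of an
  arbitrary binary resolution.

On additive matrices the output tree reproduces the generating topology
and all leaf-to-leaf path lengths to 1e-9 (tested over random 6-leaf
trees).

The bootstrap resamples alignment columns with replacement from a seeded
generator (the seed is an explicit argument — no global state), recomputes
the distance matrix via one-hot matrix products and reruns NJ; replicates
with an undefined pair are redrawn with a capped retry count.

The majority-rule consensus keeps bipartitions occurring in **more than**
the threshold fraction (default 0.5) of replicates — a split at exactly
50% is excluded — with support the rounded percentage stored as the
internal node label. Because every retained canonical block (the side not
containing the smallest leaf) occurs in a strict majority, the blocks form
a laminar family and the consensus is assembled by nesting them directly.

Identification rate at a level = 100 × (groups with ≥ 2 members that are
monophyletic with edge support ≥ `min_support`) / (groups with ≥ 2
members). Monophyly is unrooted: some edge must separate exactly the
group. Singletons are excluded and reported. With `min_support = 0` the
criterion degenerates to bare monophyly, usable on support-free trees;
whether a support floor should be required is genuinely open, so both are
exposed and the default (50, matching the consensus presentation) is
configurable.

## Indels

An indel event is a maximal run of consecutive columns with an identical
per-sequence gap pattern containing at least one gap — "simple indel
coding", which makes event counts well defined; adjacent gap columns with
different taxon patterns are distinct events. Leading/trailing all-gap
overhangs of a sequence are **missing data**, not indels: they reflect
assembly length differences, and treating them as events would let
terminal artifacts dominate the spectrum. Event counting (not gap-site
counting) is the implemented total.

Specificity requires perfect within-group uniformity: species-specific
iff the members of exactly one species all share one state (gap *or*
base) and every other sequence shows the other; variety-specific is the
analogue for one variety of a multi-variety species against the whole
remaining sample. Events satisfying both are species-specific. Events
touching a terminal-overhang region are `uninformative`; everything else
is `polymorphic`. No tolerance is applied by default — the use case is
diagnostic PCR markers, where one exception breaks the marker.

Context annotation projects the event midpoint to the ungapped reference
(gap columns inherit the preceding base's coordinate) and takes the class
of the covering feature with precedence CDS > intron > rRNA/ETS/ITS >
other; uncovered midpoints are intergenic.

## Repeats

Self-comparison by exact k-mer seeding (default k = 15) of the sequence
against itself (direct) and its reverse complement (inverted), per-diagonal
chaining, and gapless x-drop extension (match +1, mismatch −2, drop 15)
with retreat to the maximum-scoring endpoint, so exact repeats keep exact
boundaries. Pairs below `min_identity` (default 0.90, the conventional
self-BLAST cutoff) or shorter than `min_len` are discarded. An inverted
pair with a short spacer presents as a single self-mapping palindromic
run; such runs are split at the center of symmetry into their two arms,
with mismatching boundary pairs trimmed. Redundant hits — both intervals
≥ 80% contained in a longer retained pair of the same orientation — are
collapsed, retention ordered by length, then identity, then coordinates;
this is a declared algorithmic surrogate for what is usually a manual
redundancy check. Circular molecules are scanned with min_len − 1 wrapped
bases appended and coordinates reported modulo the length.

The contract, not the tool, is normative: any method finding all planted
repeats of length ≥ 2·min_len with identity ≥ min_identity + 0.03 (the
margin absorbs extension greediness) passes the recovery property.

## The synthetic-data generator

The generator emulates the study design, and its defaults are those
conditions: 16 + 10 + 6 individuals (species A; species B split into
varieties 1 and 2) drawn round-robin from 9 / 6 / 2 populations; 200-bp
windows; a 12-kb molecule as the default problem size (large enough that
every stated statistical property — gap presence, variety-level
monophyly, rank recovery of window multipliers — holds with margin, while
keeping the bootstrap fast).

Evolution is single-hit-per-branch: an ancestral sequence uniform over
{A,C,G,T} receives, on each branch of the fixed hierarchy (species split →
variety split → population → individual), independent per-site
substitutions with probability `branch divergence × window multiplier`
and equal exchange among the three alternative bases. No within-branch
back-mutation keeps expectations analytic: the per-site match probability
to the ancestor evolves as q′ = q(1−p) + (1−q)p/3 along a path, and the
expected cross-lineage p-distance is 1 − [q1·q2 + (1−q1)(1−q2)/3] — the
oracle the distance-calibration test uses (observed within 3 binomial SE).

Branch divergences default to d_s = 0.05, d_v = 0.005, d_p = 0.001,
d_i = 0.0005 substitutions/site — the scale implied by published
locus-wise ranges (inter-species ~0.1, inter-variety ~0.01, within-group
≤ 0.005) for a plastome-like molecule. Window multipliers default to iid
Gamma(shape 0.7, mean 1) draws, giving the right-skewed, hot-locus-bearing
heterogeneity seen in real profiles; explicit multiplier lists plant hot
windows deterministically. Indels follow a plan of (branch, length, count)
with defaults of ~77% ≤ 10 bp and one > 100 bp event on each of the
species-A and variety-1 branches, mirroring the observed spectrum shape;
insertions/deletions are chosen at random per event, placed
non-overlapping with a 25-bp margin so planted events are unambiguous.
Repeats (default: one exact 300-bp inverted pair and one 95%-identity
200-bp direct pair, a trnQ-IR-like configuration) are planted in the
ancestor before substitution, so leaf copies carry additional noise — the
recovery property is therefore stated on the generating (ancestral)
sequence, which the result object exposes.

The true alignment is emitted directly from the event history; no aligner
runs, so alignment error is **not** modelled. Passing tests consequently
show correctness of the statistics given a correct alignment, not
robustness to misalignment — on real data, indel counts in particular are
alignment-sensitive. Other unmodelled features of real data:
composition bias (the simulator is uniform GC), rate correlation between
adjacent windows, heterotachy, and recombination (absent, as appropriate
for a plastome).

## Problem sizes and determinism

Default analyses run 1000 bootstrap replicates on 32 × ~12 300 alignments
in seconds (distance matrices are computed via one-hot matmuls). The test
suite uses 4–10-kb molecules and 100–200 replicates; the acceptance script
uses the full 12-kb / 1000-replicate configuration plus a 3-kb rDNA-like
molecule (50-bp windows, d_s = 0.10, d_v = 0.02 — the hotter inter-variety
behaviour of rDNA spacers). Every stochastic step takes an explicit seed;
the same seed reproduces byte-identical simulator output and identical
bootstrap tree lists.
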