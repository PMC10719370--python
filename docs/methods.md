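# Methods

This note documents the models and procedures implemented in polyrearrange,
the assumptions behind them, the parameters that matter, and the design
choices made where the underlying procedures were genuinely open. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and formats

All in-memory coordinates are 0-based half-open; conversion to and from
1-based inclusive GFF3 happens only at the file boundary, so interval
arithmetic is unambiguous everywhere else. SAM is read through pysam. The
insert size of a read pair is always recomputed from mate coordinates as the
outer span (rightmost mapped base of the rightmost mate minus leftmost
mapped base of the leftmost mate, same chromosome only); the TLEN field is
ignored because its sign and gap conventions vary across aligners. MAPQ
filtering is pairwise: a pair is kept only when both mates reach the
threshold (default 20), mirroring per-read `-q` filtering applied to both
mates of a pair.

## Collinearity chaining

Anchors are homologous gene pairs; the chaining coordinate is gene rank
(0-based ordinal by start position per chromosome), which makes the
procedure independent of physical gene spacing. Before chaining, at most
`top_n = 5` subject hits are kept per query (best bit score first) and
tandem arrays — consecutive-rank genes on one chromosome all hitting the
same partner gene — are collapsed to their best-scoring member, on both
sides.

A chain must be strictly monotone in rank on both sides (increasing/
increasing = forward, increasing/decreasing = inverted) with rank gaps of at
most `max_gap_genes = 25` on each side. Chain score is the sum of anchor
scores minus a linear penalty of 1 per skipped rank; no scoring scheme is
canonical for this step, and this one is simple, monotone in chain length,
and testable. Blocks are extracted greedily: the maximum-score chain (found
by an O(n²) dynamic program per chromosome pair) is removed from the anchor
pool and emitted if it has at least `match_size = 8` anchors; chains below
`match_size` are removed but not emitted. Because extraction order does not
depend on `match_size`, raising it can only shrink the block set — a tested
invariant. Ties are broken deterministically: higher score, then leftmost
query start, then forward orientation, then lexicographically smallest rank
sequence (applied inside the DP on exact score ties, so the recovered chain
is the canonical one). The test suite checks the DP against exhaustive
enumeration of all gap-bounded monotone chains on 200 random instances.

## Rearrangement calling

Homoeolog pairing comes from the chromosome naming convention
(`Cq{i}{A|B}`; a configurable map can override it) rather than being
inferred — subgenome assignment is taken as settled input, as it is in
chromosome-scale allopolyploid assemblies.

*Translocations.* A collinear block between non-homoeologous chromosomes
marks a candidate region on each of its two sides; the carrier is the side
whose region lacks synteny with its own diploid relative. Synteny coverage
is anchor-backed: only the span of a block's anchors *inside* the region
counts, so a diploid block that merely bridges the region across a rank gap
(exactly what an inserted foreign segment produces) contributes nothing.
The coverage threshold is 0.5 of the region length. Two reciprocal carriers
between one chromosome pair (indices exchanged) merge into a single
reciprocal-translocation event with two intervals. Without diploid evidence
the subject-side region is emitted flagged `diploid-unconfirmed` rather than
dropped.

*Inversions.* Between each homoeologous pair, maximal runs of
inverted-orientation blocks are emitted as one inversion each, with
intervals on both chromosomes: self-synteny alone cannot decide which
homoeolog physically carries the inversion (that requires an outgroup, a
genetic map, or read evidence), so both regions are reported and downstream
consumers choose.

*Segmental duplications.* A block `b2` marks a duplication when another
block `b1` aligns ≥ 80% of `b2`'s query span — backed by `b1` anchors inside
it — to a partner region disjoint from `b2`'s. The two partner regions are
the copies; intra- vs inter-chromosomal follows their chromosomes.
Requiring the *query* regions to coincide is what separates duplications
from translocations: a translocated chromosome also has two disjoint
partners, but they attach to disjoint query regions. Blocks explained as
duplications are excluded from translocation calling.

*Read-mapping exchange scan.* Reciprocal homoeologous exchanges leave an
inverted pattern in diploid read-mapping rates: windows where the expected
diploid relative maps at ≤ half its chromosome-wide mean while the
alternative diploid maps at ≥ half of its own mean. Runs of at least 2 such
windows are reported. Both conditions must hold jointly — the alternative
diploid's background alone frequently clears its own halved mean.

*Accounting.* Event intervals are merged (union) per chromosome before bp
sums so overlapping events never double-count; per-event `span_bp` remains
the sum of its interval lengths. An event is *major* above 1 Mb span and
100 genes. The merge-before-sum policy is a choice (the alternative,
summing raw spans, is available for repeat accounting as `sum-raw`).

## Inversion breakpoints and panel genotyping

The genotyping logic assumes the reference assembly carries the inversion.
An accession lacking it yields read pairs whose mates map near the two
breakpoints with an outer span in a narrow gate around
`pos_right − pos_left`; an accession carrying it matches the reference, so
its pairs are concordant and individual reads span the breakpoint
coordinates. Calls: *absent* with ≥ 1 gated discordant pair joining the two
windows; *present* with zero discordant pairs and ≥ 1 read spanning each
breakpoint (an alignment strictly containing the coordinate with ≥ 1 bp on
each side); *inconclusive* otherwise. Accessions under `min_genome_coverage
= 5×` are excluded before calling. For the published Cq3B pericentromeric
inversion the defaults are its breakpoint coordinates 11,136,405 and
63,361,214 with counting windows Cq3B:11,136,100–11,137,000 and
63,360,700–63,361,700 and insert gate 52,223,700–52,225,600 bp, which
brackets the breakpoint span of 52,224,809 bp; a slightly different right
coordinate (63,361,684) appears in some evidence tracks, and the windows are
wide enough that the difference does not change counting. For synthetic
genomes, window half-width defaults scale with the insert distribution
(mean + 4 sd) so windows capture the mate pile-up.

Breakpoint *location* exploits the fact that no read maps across a
breakpoint end-to-end: discordant-mate alignments abut it, ends piling up
just below and starts just above, and the breakpoint itself is crossed by
zero alignments (the sharp coverage interruption, expressed at single-base
resolution). Within each candidate region (≤ ~50 kb, from synteny or map
breaks) the estimator takes the pairs joining the two regions, restricts to
candidate positions crossed by no alignment, scores each by abutment within
1 kb — balanced evidence (ends below *and* starts above) first — and
returns the midpoint between the largest end below and the smallest start
above the winner; ties resolve toward the inversion interior. On simulated
panels this lands within a few bp of truth; the tested contract is one read
length. The insert gate returned with located breakpoints brackets the
observed joining-pair spans (± 100 bp margin). No discordant pairs in the
candidate regions is an error, not an empty answer.

## Repeat dynamics

Copy number is the count of annotated elements; bp totals merge overlapping
same-family copies (union) before summing, preventing double counts from
nested or fragmented annotations — the merge policy is configurable
(`merge` | `sum-raw`) since annotation post-processing conventions differ.
Partitions (subgenome A, subgenome B, each diploid) are disjoint chromosome
sets, so per-family partition totals sum exactly to the whole-genome rollup
under the same policy (a tested conservation property). Superfamily rollups
sum family totals without re-merging across families.

LTR enrichment between subgenomes uses log2(copies_B / copies_A):
`|log2FC| ≥ 1` (two-fold) calls the family enriched on the larger side, a
zero on one side makes it subgenome-specific (no pseudocount — specificity
is information, not a numerical nuisance), and "highly repeated" means
whole-genome copies above the mean per-family LTR copy number of the input
(a data-derived threshold, since any fixed number is dataset-specific). The
classification is symmetric under swapping subgenome labels, which the
tests verify, along with recovery of planted biases across seeds. Only
families with a complete full-length structure are classified by default.
Window density tracks count features by start position in 1-Mb windows,
keeping the last partial window.

## Genetic-vs-physical map concordance

Markers are placed by exact search of their flanking sequence (default
500 bp, marker at the midpoint) against the assembly, both strands; only a
single hit places a marker, ties are reported `ambiguous` and misses
`absent`. Exact matching is appropriate at synthetic scale; for real data a
precomputed alignment table can replace the search without changing
downstream logic.

Break detection first normalizes each chromosome's global orientation by
the sign of the Spearman correlation between cM and bp (a wholly reversed
chromosome is an assembly orientation choice, not a rearrangement). After
sorting by physical position, runs of ≥ 2 adjacent markers with decreasing
cM mark reversed segments; each internal run boundary is reported as the
physical gap between the flanking markers, which by construction contains
the true breakpoint. The published practice for this step is visual
inspection of marker plots; the run rule is this package's explicit,
parameterized operationalization, and it is invariant (tested) under
reversing either the genetic or the physical axis. Chromosomes with fewer
than 10 placed markers are skipped.

## Synthetic data generator

The generator emulates the features these procedures consume: two
subgenomes of ordered gene arrays descended from two diploid gene orders
(3 chromosomes × 200 genes × 1 Mb per subgenome by default — large enough
that every planted event exceeds the 8-anchor block threshold with margin,
small enough for second-scale tests); gene density rising toward telomeres
(U-shaped Beta(0.5, 0.5) allocation of intergenic slack); TE density rising
toward centromeres (Beta(3, 3) placement); homologous pairs emitted as a
BLAST-style anchor table from ancestral gene identity with scores ~U(900,
1100); planted events applied to gene orders before coordinates are drawn,
with exact truth intervals recorded from the resulting gene bounds.

Planted defaults: a reciprocal tail swap of 30/25 genes between Cq1B and
Cq2B, a 52-gene pericentromeric inversion on Cq3B (echoing the scale, in
gene terms, of the studied inversion), and a 12-gene intra-chromosomal
duplication on Cq2B. TE families cover the enrichment classes (B-enriched,
A-enriched, not-enriched, B-specific, A-specific, plus a non-LTR family)
with exact planted copy numbers, so classification truth is by
construction.

Panel reads are emitted as already-placed SAM records: the pipeline
consumes alignments, and mapping itself is outside its scope. A non-carrier
accession is modeled by re-inverting the reference segment and projecting
mate coordinates back through the inversion; reads individually straddling
a boundary are dropped as unmappable end-to-end, which produces both the
discordant joining pairs (outer span ≈ breakpoint span ± insert) and the
sharp coverage interruption the breakpoint locator relies on. Default
library geometry: 100-bp reads, insert 500 ± 50 bp (the insert distribution
of the emulated resequencing libraries is not published; these are ordinary
short-insert values and are free parameters). Depth 10× for the default
panel; at 10× the expected number of gated joining pairs per non-carrier is
≈ depth · (insert − 2·read)/(2·read) per boundary ≈ 15, so genotyping is
far from the decision boundary, while 0.1× accessions fall under the 5×
coverage floor and are excluded.

For the diploid read-mapping tracks, an exchanged region swaps the two
baselines (expected diploid 0.9 → 0.2, alternative 0.2 → 0.9, Gaussian
noise on top): a homoeologous exchange replaces the region's sequence, so
the expected diploid's mapping falls to the cross-subgenome background
while the alternative's rises to full — an exchange of levels, not a mere
halving, which also keeps the detection rule's margins ≫ the 0.05 noise sd.
An explicit drop level is available for constructing edge cases.

Determinism: one global seed, with every component (coordinates, anchors,
TEs, reads, sequences, markers, tracks) drawing from its own derived
substream (per-chromosome streams are keyed by CRC32, not Python's
randomized `hash`), so each output file is byte-stable regardless of which
other outputs are generated — a tested property.

What the generator does *not* emulate — and therefore what passing tests do
not show about real data: sequencing errors and base qualities, mapping
ambiguity in repeats (all synthetic reads map uniquely at MAPQ 60),
fractionation-driven gene loss, tandem-array proliferation, tissue-specific
annotation noise, and assembly gaps. Results on real data depend on the
upstream aligner and annotation quality in ways these tests cannot certify.

## Degenerate inputs and edge behavior

Empty annotation files yield empty results, not errors; an empty assembly
or a marker table with missing columns is an error. Zero totals produce NA
percentages. A collinearity summary over zero blocks is 0%. Unpaired SAM
records at EOF are dropped with a warning. Chromosomes absent from a
subgenome map fall back to name parsing, then to `none`. `match_size < 2`
is rejected.

## Known limitations

Translocation carriers cannot be resolved without diploid evidence; the
flagged convention (subject side) is arbitrary by necessity. Inversion
events report both homoeologous regions rather than deciding a carrier.
Breakpoint location assumes full-length alignments (no split-read or
soft-clip modeling). The map-break rule reports marker-gap intervals, so
its resolution is the local marker density. Repeat bp accounting merges
only within families; overlapping annotations across families still
double-count in superfamily rollups.
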