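# Methods

This note records the models, conventions and design choices behind
`founderpan`, in the order of the pipeline.

## Variant graph and reference-guided MSA

Coordinates are 1-based and inclusive throughout (VCF convention); graph
nodes are labeled with reference coordinates, and segments are half-open
node intervals `[a, b)`. The node set of the per-chromosome DAG is the
union of `{1, R+1}` with every variant's start and exclusive end
(`POS + |REF|`); consecutive nodes are joined by reference edges labeled
with the intervening reference substring, and each alternative allele
adds one edge from start to end. Duplicate alternative edges (same
source, target and label, e.g. from two VCF records) are merged.
Variants sharing a start are ordered by `(start, end, alt)` to make
construction deterministic. The node count is at most `2v + 2` for `v`
variants.

Aligned positions are a longest-path DP over label lengths in node
order; the gap rule appends `aligned(r) − aligned(q) − |label|` gap
characters after traversing edge `(q, r, label)`. Rows are therefore
equal-width by construction, and ungapping a row reproduces the
haplotype exactly (property-tested against an independent
direct-splicing oracle).

Phasing: `|` is required in strict mode. Lenient mode treats `/` as
phased with a warning — appropriate for haploid data, where phasing is
vacuous. Overlapping variants chosen on one haplotype are an error
naming both records; an opt-in flag drops the later-starting record
with a warning instead. Missing allele calls (`.`) are treated as
reference with a warning. Symbolic alleles (`<DEL>`, breakends) are
rejected; the gap character is `-`, and `N` is an ordinary sequence
character.

## Segmentation

A reference edge is a bridge iff no alternative edge spans it; the cut
candidates are the interior bridge nodes. `d(q, r)` counts distinct
*restrictions of the input sequences* (the haplotypes plus the
reference, each with weight 1) to `[q, r)` — not combinatorial graph
paths; the worked example forces this reading (its first segment has 3
distinct subsequences, not the 6 graph paths).

The DP minimizes the maximum per-segment `d` subject to every segment
spanning at least `L` reference positions. The base case is the uncut
prefix, `D(r) = d(1, r)`, feasible when `r − 1 ≥ L`; the no-cut and cut
options compete in the minimum. When no segmentation satisfies the
length constraint at the sink, the single uncut segment `[1, R+1)` is
returned as the fallback. Among options with equal `D`, the largest
(most recently cut) last cut wins, with "no cut" ranked below any cut;
the rule is applied recursively during backtracking. Memoized `d`
lookups make the DP `O(|Q|²)` evaluations; an exhaustive search over
all bridge-node subsets serves as the test oracle at small sizes.

## Founder joining

Per segment, distinct subsequences are seeded into slots in descending
occurrence order (count ties broken lexicographically). For each
consecutive segment pair, distinct concatenated windows are processed
in descending count order: an edge connects the two slots when both are
unconnected; if a side's slot is taken but an available (empty) slot
exists, the subsequence is duplicated into it; otherwise the window is
skipped. Remaining slots are paired in ascending index. When one
subsequence occupies several slots (duplicates from an earlier
pairing), the lowest-indexed unconnected slot is its representative —
a deterministic refinement required for chains across more than two
segments. The result is independent of haplotype input order.

Slots still empty after joining are filled by duplicating that
segment's subsequences cyclically in descending count order (default,
matching the worked example's duplicated first-segment subsequence); a
flag switches to N-fill, where the slot becomes an all-`N` block
spanning the segment's MSA columns. Both behaviors are provided because
duplication maximizes usable index sequence while N-fill marks the
slot as padding.

`f` defaults to the segmentation bound `max d(q, r)` and values below
it are rejected. The coverage property motivating `L` holds by
construction and is tested: every haplotype's per-segment subsequence
occurs in at least one founder, hence any read landing within one
segment has an exact home in the founder set.

## LZ kernel

The parse dialect is a greedy longest-previous-factor over the
separator-protected concatenation of the inputs: a copy's source must
lie entirely before the copy's start (no self-overlap) and phrases never
cross sequence boundaries; unmatched characters become literal runs.
The factor search is a per-position binary search over `str.find`
windows — quadratic in the worst case, which is adequate at the scales
this package targets (founder panels up to a few hundred kilobases).

The kernel keeps literals and copies of length ≤ 2P whole; longer
copies contribute their first and last P characters as detached pieces
(contiguous retained runs merged, emitted as separate FASTA records so
aligners cannot match across excision points). The operative contract
is P-mer coverage: every substring of length ≤ P of every input occurs
in some kernel piece. Because an excised copy's own source region may
also have been excised, a post-hoc verifier re-retains offending
phrases whole until the property holds; the property is tested
exhaustively on randomized repeat-rich inputs. Reads are treated as
single-ended against the kernel, since pieces are detached.

## Support matrix and ad hoc reference

One best alignment per read: primary records ranked by aligner score
(`AS` tag), then mapping quality, then input order; unmapped, secondary
and supplementary records are ignored. A best alignment spanning
founder positions `p..q` on row `i` increments `M[i]` over the
inclusive MSA column range of `p..q`, interior gap columns included.
Kernel-piece alignments are lifted through the provenance map first.

Extraction takes the per-column argmax with ties to the lowest row
index; the original reference is always row 0, so zero support yields
the reference identically. Founder deletions are realized when a gap
column wins (the base is dropped) and founder insertions when a non-gap
insertion column wins; read-level indels inside alignments are not
re-examined. `M` is held dense (`m × n` int64), fine at the intended
scale; the extraction API touches columns independently, so a streamed
implementation could replace it without interface changes.

## Projection

Caller records are validated against the ad hoc sequence, lifted to MSA
columns, and re-referenced: REF becomes the original reference
characters across the spanned columns (which may lengthen REF across a
founder-deleted region); ALT and genotypes are kept as called. A record
with no reference image (inside a founder insertion) is anchored to the
preceding reference base — or the following one at the sequence start.
All emitted records are left-aligned and trimmed, and every REF is
re-checked against the reference before writing.

Embedded variants are the maximal MSA column runs where the ad hoc row
differs from the reference row, converted to records with the same
anchoring rules. Genotypes: with no overlapping caller record
(intersecting reference intervals after projection), every chromosome
copy carries the difference; otherwise the caller's non-zero genotype
values are counted per sample, subtracted from the ploidy, and the
remainder becomes the embedded record's non-zero count. A difference
whose remainder is zero for all samples is suppressed rather than
emitted as an all-reference record. Partially overlapping embedded and
caller records are both emitted, flagged with `ADHOC_OVERLAP`, rather
than merged. The arithmetic is applied per sample; ploidy is a
parameter (default 2, haploid mode for bacterial-style data).

## Simulator

The generational model doubles the population every generation
(generation g holds 2^g genomes), matching clonal division with both
daughters retained. Each child inherits its parent's substitutions and
mutates each locus independently with the configured per-generation
probability, drawing the new base uniformly from the three
alternatives; a locus may mutate repeatedly along a lineage, and a
reversion to the reference base removes the record. Substitutions are
the only event type. The final generation is exported as a haploid
multi-sample VCF, and a round-trip test confirms the VCF regenerates
every genome through the variant-graph path.

Read simulation draws fragment lengths from a clamped normal
distribution (defaults 300 ± 25) and fragment starts uniformly; both
mates are emitted with independent per-base substitution errors at the
configured rate (constant quality strings; no indel or
platform-specific error profile). A truth SAM with the error-free
placements lets the support/extraction stages be tested without an
external aligner. All stochastic operations take an explicit seed and
are byte-reproducible; there is no hidden global RNG.

What the simulator does *not* emulate: linkage beyond shared ancestry,
indels and structural variants, coverage biases, quality-score
structure and mapping ambiguity from an actual aligner. Passing tests
therefore demonstrate algorithmic correctness of the pipeline stages,
not calling accuracy on real sequencing data.

## Problem sizes in the test and acceptance runs

The worked example (18 bp reference, 5 variants, 5 haplotypes) is
exact and runs in milliseconds. Property suites use randomized
references of 60–400 bp with up to 20 variants, LZ inputs up to 2 kb
with planted repeats (P up to 20), panels of 8–32 genomes on references
of 300 bp–10 kb, and read sets up to ~60 kb × 8× coverage — sizes
chosen so each oracle (exhaustive path enumeration, subset search,
naive factor scans, quadratic DP) remains tractable while exercising
the same code paths as production-scale inputs.

## Known limitations

- One graph per chromosome; no symbolic/structural alleles and no `*`
  overlapping-deletion alleles.
- The segmentation DP is quadratic in the number of bridge nodes;
  very variant-dense megabase inputs would need the pruning structure
  sketched in the complexity discussion rather than plain memoization.
- The LZ parse is not the RLZ/LZ77 dialect of any specific external
  indexer; the P-mer coverage contract, not the phrase boundaries, is
  what downstream stages rely on.
- Embedded-variant genotype subtraction assumes caller records and
  embedded differences overlap cleanly; partially overlapping indels
  are reported side by side with a flag, not reconciled.
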