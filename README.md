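# founderpan

Founder-sequence pangenome construction and variant projection for
reference-guided resequencing workflows.

Single-reference variant calling is biased toward the alleles of the
chosen reference. A pragmatic remedy is to align reads against a small
panel of *founder sequences* — artificial haplotypes assembled from
shared segments of known haplotypes so that a handful of founders covers
all observed local variation — then collapse the read support into one
*ad hoc reference* for a conventional caller, and finally project the
calls back to the original reference coordinates. `founderpan`
implements the bespoke computational core of that workflow for anyone
building pangenome-aware pipelines around standard tools (BWA-MEM /
Bowtie 2 for alignment, GATK / BCFtools for calling, which remain
external):

1. **VCF → multiple alignment** (`founderpan.msa_graph`). Phased
   variants on a reference of length *R* induce a directed acyclic
   variant graph with nodes at variant start/end coordinates (plus 1 and
   *R*+1), reference edges along the backbone and one labeled edge per
   alternative allele. The *aligned position* of each node —
   `aligned(r) = max over in-edges (q,r,ℓ) of aligned(q) + |ℓ|`, with
   `aligned(1) = 1` — pins every haplotype into an equal-width,
   reference-guided MSA in linear time.
2. **Founder reconstruction** (`founderpan.founder`). A *bridge* is a
   reference edge on every source-to-sink path; bridge nodes are the
   legal cut points. With `d(q, r)` the number of distinct haplotype
   restrictions between cut-eligible nodes `q` and `r`, the dynamic
   program
   `D(r) = min over q (r − q ≥ L) of max{D(q), d(q, r)}`
   chooses cuts minimizing the worst per-segment distinct count, subject
   to a minimum segment size `L`; ties prefer the most recently cut
   final segment. Segments are then joined into
   `f ≥ max d(q, r)` founders by a greedy bipartite matching that keeps
   the most frequent local haplotype combinations contiguous.
3. **LZ kernel** (`founderpan.kernel`). The founders are factorized into
   literal and copying phrases; for read length *P*, copies longer than
   2*P* keep only their first and last *P* characters. Every substring
   of length ≤ *P* still occurs in some kernel piece, so short-read
   alignment against the (much smaller) kernel loses nothing; a
   provenance map lifts kernel alignments back onto founder coordinates.
4. **Ad hoc reference** (`founderpan.adhoc`). Best alignments increment
   an *m* × *n* support matrix over founder rows and MSA columns; per
   column the heaviest row's character is emitted (gaps emit nothing),
   mimicking recombination between founders. Ties favor the reference
   row, so zero coverage reproduces the original reference.
5. **Projection** (`founderpan.project`). Calls made against the ad hoc
   reference are rewritten to original coordinates (REF re-read from the
   reference across the matching MSA columns), and ad-hoc-embedded
   differences are reported with genotypes obtained by subtracting the
   caller's non-zero genotype count from the ploidy.
6. **Simulation** (`founderpan.simfix`). A generational substitution
   simulator (population doubles every generation: 2^g genomes at
   generation g), a paired-end read simulator with a fixed per-base
   error rate and truth alignments, the packaged worked-example variant
   table, and a Levenshtein evaluator.

## Worked example

The packaged example uses reference `TTCTGGGAGGCAGTTACC` (R = 18) with
five variants carried by five haploid samples:

```python
import founderpan as fp

fix = fp.table1_fixture()
graph = fp.build_variant_graph(fix.reference, fix.records)
paths = fp.haplotype_paths(graph, fix.records, fix.samples)

seg = fp.optimal_segmentation(graph, paths, L=4)
print(seg.cuts, seg.sizes, seg.D_value)

_, table, fset, fmsa, seqs = fp.reconstruct_founders(
    graph, fix.records, fix.samples, L=4, f=4
)
for label, row in zip(fmsa.labels, fmsa.rows):
    print(f"{label:9s} {row}")
```

prints

```
[7, 12] [6, 5, 7] 4
REF       T--TCTG-G--GAGGCAGTTACC
founder1  T--TCAAAAAAGAGGCAGTTACC
founder2  TAATCTCCG--GAGGCT----CC
founder3  T--TCTG-G--GAGGCAGTTA-C
founder4  T--TCAAAAAAGAGGCAGTTT-C
```

Reading: with minimum segment size `L = 4` the best cuts are the bridge
nodes 7 and 12, giving segments spanning 6, 5 and 7 reference positions
whose worst distinct-subsequence count is `D = 4`, so four founders
suffice. The first segment has only three distinct subsequences, so one
(`TTCAAAAAA`, the most frequent) is duplicated across founders. All
rows share the 23-column MSA; ungapping any row yields that founder's
sequence. The same pipeline is available from the shell
(`founderpan vcf2msa | founders | kernel | adhoc | project | simulate`).

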