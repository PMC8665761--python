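"""Synthetic data: generational mutation panels, read simulation and the
small worked-example fixture.

The generational simulator emulates clonally dividing bacteria: starting
from a single genome equal to the reference, every genome in generation
g - 1 produces two children in generation g, each inheriting its
parent's substitutions and adding new ones — every locus mutates
independently with the given per-generation rate, the new base drawn
uniformly from the three alternatives.  Generation g therefore holds
exactly 2**g genomes.  The final generation is exported as a haploid
multi-sample VCF so the whole founder pipeline can be exercised without
external data.

Read simulation draws paired-end fragments uniformly from a sequence,
applies a fixed per-base substitution error rate, and writes FASTQ plus
a truth SAM so downstream support accumulation can be tested without an
external aligner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam

from .msa_graph import VariantRecordLite

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenerationalPanel:
    """2**g genomes described as substitution sets over a reference."""

    reference: str
    generations: int
    mutations: list[dict[int, str]]  # per genome: 1-based locus -> base
    seed: int
    sample_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.sample_names = [
            f"g{self.generations}s{i + 1}" for i in range(len(self.mutations))
        ]

    @property
    def n_genomes(self) -> int:
        return len(self.mutations)

    def sequence(self, i: int) -> str:
        seq = list(self.reference)
        for pos, base in self.mutations[i].items():
            seq[pos - 1] = base
        return "".join(seq)

    def to_variant_records(self) -> list[VariantRecordLite]:
        """Haploid multi-sample SNP records for the final generation."""
        loci = sorted({pos for m in self.mutations for pos in m})
        records: list[VariantRecordLite] = []
        for pos in loci:
            ref_base = self.reference[pos - 1]
            alts = sorted({m[pos] for m in self.mutations if pos in m})
            genotypes = {
                name: (alts.index(m[pos]) + 1 if pos in m else 0)
                for name, m in zip(self.sample_names, self.mutations)
            }
            records.append(
                VariantRecordLite(
                    pos=pos,
                    ref_allele=ref_base,
                    alt_alleles=tuple(alts),
                    genotypes=genotypes,
                    id=f"m{pos}",
                )
            )
        return records

    def write_vcf(self, path: str, chrom: str = "ref") -> None:
        _write_haploid_vcf(
            path, chrom, self.reference, self.to_variant_records(), self.sample_names
        )


def _write_haploid_vcf(
    path: str,
    chrom: str,
    reference: str,
    records: list[VariantRecordLite],
    sample_names: list[str],
) -> None:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={len(reference)}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in sample_names:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in records:
            vrec = out.new_record(
                contig=chrom,
                start=rec.pos - 1,
                alleles=(rec.ref_allele, *rec.alt_alleles),
                id=rec.id,
            )
            for s in sample_names:
                vrec.samples[s]["GT"] = (rec.genotypes.get(s, 0),)
                vrec.samples[s].phased = True
            out.write(vrec)


def simulate_generations(
    reference: str, mutation_rate: float, generations: int, seed: int
) -> GenerationalPanel:
    """Run the doubling-per-generation substitution simulator.

    ``mutation_rate`` is the per-locus, per-generation substitution
    probability.  A locus already mutated in a lineage may mutate again
    (uniformly over the three alternatives to its current base); a
    mutation restoring the reference base removes the record.
    """
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation rate must be in [0, 1]")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    reference = reference.upper()
    rng = np.random.default_rng(seed)
    R = len(reference)
    genomes: list[dict[int, str]] = [{}]
    for _ in range(generations):
        children: list[dict[int, str]] = []
        for parent in genomes:
            for _ in range(2):
                child = dict(parent)
                n_mut = rng.binomial(R, mutation_rate)
                if n_mut:
                    loci = rng.choice(R, size=n_mut, replace=False) + 1
                    for pos in sorted(int(p) for p in loci):
                        current = child.get(pos, reference[pos - 1])
                        options = [b for b in _BASES if b != current]
                        base = options[rng.integers(len(options))]
                        if base == reference[pos - 1]:
                            child.pop(pos, None)
                        else:
                            child[pos] = base
                children.append(child)
        genomes = children
    return GenerationalPanel(reference, generations, genomes, seed)


@dataclass
class SimulatedRead:
    name: str
    mate: int  # 1 or 2
    seq: str
    ref_name: str
    pos: int  # 1-based leftmost aligned position
    reverse: bool


@dataclass
class SimulatedReadSet:
    """Paired-end reads with per-read truth placements."""

    reads: list[SimulatedRead]
    read_length: int
    error_rate: float
    coverage: float
    seed: int
    ref_name: str
    ref_length: int

    @property
    def n_pairs(self) -> int:
        return len(self.reads) // 2

    def write_fastq(self, path1: str, path2: str) -> None:
        qual = "I" * self.read_length
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for r in self.reads:
                fh = f1 if r.mate == 1 else f2
                fh.write(f"@{r.name}/{r.mate}\n{r.seq}\n+\n{qual}\n")

    def write_sam(self, path: str, extra_refs: dict[str, int] | None = None) -> None:
        """Truth alignments; both mates mapped with full-length match CIGAR."""
        refs = {self.ref_name: self.ref_length}
        if extra_refs:
            refs.update(extra_refs)
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in refs.items()],
        }
        ref_ids = {n: i for i, n in enumerate(refs)}
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for r in self.reads:
                a = pysam.AlignedSegment()
                a.query_name = r.name
                a.query_sequence = r.seq if not r.reverse else revcomp(r.seq)
                a.flag = (
                    0x1 | 0x2
                    | (0x40 if r.mate == 1 else 0x80)
                    | (0x10 if r.reverse else 0x20)
                )
                a.reference_id = ref_ids[r.ref_name]
                a.reference_start = r.pos - 1
                a.mapping_quality = 60
                a.cigarstring = f"{self.read_length}M"
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * self.read_length
                )
                out.write(a)


def simulate_reads(
    sequence: str,
    read_length: int,
    error_rate: float,
    coverage: float,
    seed: int,
    insert_mean: float = 300.0,
    insert_sd: float = 25.0,
    name: str = "seq",
) -> SimulatedReadSet:
    """Uniform paired-end fragments with substitution errors.

    The truth SAM records the error-free placement of each mate; the
    read sequences carry per-base substitution errors at ``error_rate``.
    """
    sequence = sequence.upper()
    R = len(sequence)
    if read_length > R:
        raise ValueError("read length exceeds sequence length")
    if insert_mean < read_length:
        warnings.warn("insert size shorter than read length; clamped", stacklevel=2)
        insert_mean = float(read_length)
    rng = np.random.default_rng(seed)
    n_pairs = int(round(coverage * R / (2 * read_length)))
    reads: list[SimulatedRead] = []

    def mutate(seq: str) -> str:
        errs = np.flatnonzero(rng.random(len(seq)) < error_rate)
        if not len(errs):
            return seq
        out = list(seq)
        for j in errs:
            options = [b for b in _BASES if b != out[j]]
            out[j] = options[rng.integers(3)]
        return "".join(out)

    for i in range(n_pairs):
        frag = int(round(rng.normal(insert_mean, insert_sd)))
        frag = max(read_length, min(frag, R))
        start = int(rng.integers(0, R - frag + 1))
        fwd = sequence[start : start + read_length]
        rev_start = start + frag - read_length
        rev = revcomp(sequence[rev_start : rev_start + read_length])
        rname = f"sim{i}"
        reads.append(
            SimulatedRead(rname, 1, mutate(fwd), name, start + 1, reverse=False)
        )
        reads.append(
            SimulatedRead(rname, 2, mutate(rev), name, rev_start + 1, reverse=True)
        )
    return SimulatedReadSet(
        reads, read_length, error_rate, coverage, seed, name, R
    )


TABLE1_REFERENCE = "TTCTGGGAGGCAGTTACC"
_TABLE1_ROWS = [
    # pos, id, ref, alts, genotypes of s1..s5
    (1, "a", "T", ("TAA",), (0, 0, 1, 1, 0)),
    (4, "b", "TGG", ("AAAAAA",), (1, 1, 0, 0, 1)),
    (5, "c", "G", ("CC",), (0, 0, 1, 1, 0)),
    (12, "d", "AGTTA", ("T",), (0, 0, 0, 1, 1)),
    (16, "e", "AC", ("T", "A"), (0, 1, 2, 0, 0)),
]
TABLE1_SAMPLES = ["s1", "s2", "s3", "s4", "s5"]
TABLE1_HAPLOTYPES = {
    "s1": "TTCAAAAAAGAGGCAGTTACC",
    "s2": "TTCAAAAAAGAGGCAGTTTC",
    "s3": "TAATCTCCGGAGGCAGTTAC",
    "s4": "TAATCTCCGGAGGCTCC",
    "s5": "TTCAAAAAAGAGGCTCC",
}


@dataclass
class Table1Fixture:
    """The five-record, five-sample haploid worked example."""

    reference: str
    records: list[VariantRecordLite]
    samples: list[str]
    haplotypes: dict[str, str]

    def write_vcf(self, path: str, chrom: str = "ref") -> None:
        _write_haploid_vcf(path, chrom, self.reference, self.records, self.samples)

    def write_reference_fasta(self, path: str, chrom: str = "ref") -> None:
        with open(path, "w") as fh:
            fh.write(f">{chrom}\n{self.reference}\n")


def table1_fixture() -> Table1Fixture:
    """Byte-exact worked-example fixture (reference length 18)."""
    records = [
        VariantRecordLite(
            pos=pos,
            ref_allele=ref,
            alt_alleles=alts,
            genotypes=dict(zip(TABLE1_SAMPLES, gts)),
            id=vid,
        )
        for pos, vid, ref, alts, gts in _TABLE1_ROWS
    ]
    return Table1Fixture(
        TABLE1_REFERENCE, records, list(TABLE1_SAMPLES), dict(TABLE1_HAPLOTYPES)
    )


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (row-vectorized dynamic program)."""
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    prev = np.arange(len(b) + 1, dtype=np.int64)
    idx = np.arange(len(b) + 1, dtype=np.int64)
    for i, ch in enumerate(a.encode("ascii"), start=1):
        cur = np.empty_like(prev)
        cur[0] = i
        sub = prev[:-1] + (bb != ch)
        dele = prev[1:] + 1
        cur[1:] = np.minimum(sub, dele)
        # close under insertions: cur[j] = min_{j' <= j} cur[j'] + (j - j')
        cur = np.minimum(cur, np.minimum.accumulate(cur - idx) + idx)
        prev = cur
    return int(prev[-1])
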