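"""Reference-guided multiple alignment from phased VCF variants.

A set of phased variant records against a common reference encodes one
pairwise alignment per haplotype.  Those pairwise alignments are made
mutually consistent by routing every haplotype through a directed acyclic
*variant graph*: nodes sit at the unique start and end positions of the
variants (plus the two boundary positions ``1`` and ``R + 1`` for a
reference of length ``R``), consecutive nodes are joined by *reference
edges* labeled with the intervening reference substring, and every
alternative allele contributes one extra labeled edge from its start node
to its end node.

Each node is then given an *aligned position*: the multiple-alignment
column obtained by a longest-path dynamic program over label lengths.
Emitting a haplotype row is a single walk along its path, padding after
each edge with enough gap characters to reach the target node's aligned
position.  The result is an equal-width, reference-guided MSA whose rows
ungap back to the exact haplotype sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    FounderPanError,
    OverlappingVariantError,
    ReferenceMismatchError,
    UnphasedGenotypeError,
    UnsupportedAlleleError,
)

GAP = "-"
REFERENCE_LABEL = "REF"
_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class Edge:
    """A labeled edge of the variant graph.

    ``kind`` is ``"reference"`` for edges of the reference backbone and
    ``"alternative"`` for alt-allele edges.  Node coordinates are 1-based
    reference positions; an edge from ``source`` to ``target`` replaces
    reference positions ``[source, target)`` with ``label``.
    """

    source: int
    target: int
    label: str
    kind: str
    variant_id: str | None = None


@dataclass
class VariantRecordLite:
    """A minimal phased variant record.

    ``genotypes`` maps a haplotype label (sample name, or
    ``"{sample}_{copy}"`` for multi-copy samples) to an allele index,
    0 denoting the reference allele.
    """

    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: dict[str, int] = field(default_factory=dict)
    id: str | None = None

    @property
    def end(self) -> int:
        """Exclusive end position on the reference (``pos + len(REF)``)."""
        return self.pos + len(self.ref_allele)

    @property
    def label(self) -> str:
        return self.id if self.id is not None else f"{self.pos}:{self.ref_allele}"


@dataclass
class VariantGraph:
    """Per-chromosome DAG of reference and alternative edges.

    ``nodes`` is strictly increasing and always contains ``1`` and
    ``R + 1``.  Every node but the last has exactly one outgoing
    reference edge to the next node; concatenating reference-edge labels
    yields the reference sequence.
    """

    reference: str
    nodes: list[int]
    ref_edges: dict[int, Edge]
    alt_edges: list[Edge]
    aligned_pos: dict[int, int] = field(default_factory=dict)

    @property
    def R(self) -> int:
        return len(self.reference)

    @property
    def width(self) -> int:
        """Width of the induced MSA."""
        if not self.aligned_pos:
            aligned_positions(self)
        return self.aligned_pos[self.R + 1] - 1

    def alt_edge(self, source: int, target: int, label: str) -> Edge:
        for e in self.alt_edges:
            if e.source == source and e.target == target and e.label == label:
                return e
        raise KeyError((source, target, label))

    def in_edges(self, node: int) -> list[Edge]:
        edges = [e for e in self.ref_edges.values() if e.target == node]
        edges.extend(e for e in self.alt_edges if e.target == node)
        return edges


@dataclass
class ReferenceGuidedMSA:
    """Equal-width gapped rows over ``{A,C,G,T,N,-}`` with row labels."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"rows have unequal widths: {sorted(widths)}")
        self._cum: dict[int, np.ndarray] = {}

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def ungapped(self, row_index: int) -> str:
        return self.rows[row_index].replace(GAP, "")

    def _cumulative(self, row_index: int) -> np.ndarray:
        cum = self._cum.get(row_index)
        if cum is None:
            arr = np.frombuffer(self.rows[row_index].encode("ascii"), dtype=np.uint8)
            cum = np.cumsum(arr != ord(GAP))
            self._cum[row_index] = cum
        return cum

    def column_of(self, row_index: int, position: int) -> int:
        """MSA column (1-based) of the ``position``-th non-gap character."""
        cum = self._cumulative(row_index)
        total = int(cum[-1]) if len(cum) else 0
        if position < 1 or position > total:
            raise IndexError(
                f"position {position} outside ungapped row of length {total}"
            )
        return int(np.searchsorted(cum, position)) + 1

    def position_of(self, row_index: int, column: int) -> int | None:
        """Ungapped position (1-based) at ``column``, or None on a gap."""
        if column < 1 or column > self.width:
            raise IndexError(f"column {column} outside MSA of width {self.width}")
        if self.rows[row_index][column - 1] == GAP:
            return None
        return int(self._cumulative(row_index)[column - 1])

    def write_fasta(self, path: str) -> None:
        records = [
            SeqRecord(Seq(row), id=label, description="")
            for label, row in zip(self.labels, self.rows)
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def read_fasta(cls, path: str) -> "ReferenceGuidedMSA":
        labels, rows = [], []
        for rec in SeqIO.parse(path, "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(labels, rows)


def _check_variant(reference: str, v: VariantRecordLite) -> None:
    R = len(reference)
    if v.pos < 1:
        raise FounderPanError(f"variant {v.label}: position {v.pos} < 1")
    if v.end > R + 1:
        raise FounderPanError(
            f"variant {v.label}: end {v.end - 1} exceeds reference length {R}"
        )
    for allele in (v.ref_allele, *v.alt_alleles):
        if not allele or not set(allele) <= _ALPHABET:
            raise UnsupportedAlleleError(
                f"variant {v.label}: unsupported allele {allele!r}"
            )
    expected = reference[v.pos - 1 : v.end - 1]
    if v.ref_allele != expected:
        raise ReferenceMismatchError(
            f"variant {v.label} at {v.pos}: REF {v.ref_allele!r} does not match "
            f"reference {expected!r}"
        )


def build_variant_graph(
    reference: str, variants: list[VariantRecordLite]
) -> VariantGraph:
    """Build the variant DAG from validated records.

    Node set: boundaries 1 and R+1 plus every unique variant start and
    (exclusive) end.  Duplicate alternative edges (same source, target and
    label) are merged.
    """
    reference = reference.upper()
    R = len(reference)
    positions = {1, R + 1}
    for v in variants:
        _check_variant(reference, v)
        positions.add(v.pos)
        positions.add(v.end)
    nodes = sorted(positions)

    ref_edges: dict[int, Edge] = {}
    for q, r in zip(nodes, nodes[1:]):
        ref_edges[q] = Edge(q, r, reference[q - 1 : r - 1], "reference")

    seen: dict[tuple[int, int, str], Edge] = {}
    # deterministic order: (start, end, alt string) per the sorting contract
    for v in sorted(variants, key=lambda v: (v.pos, v.end, v.alt_alleles)):
        for alt in v.alt_alleles:
            key = (v.pos, v.end, alt)
            if key not in seen:
                seen[key] = Edge(v.pos, v.end, alt, "alternative", v.id)
    graph = VariantGraph(reference, nodes, ref_edges, list(seen.values()))
    aligned_positions(graph)
    return graph


def aligned_positions(graph: VariantGraph) -> dict[int, int]:
    """Longest-path MSA coordinate per node.

    ``aligned_pos(1) = 1``; for every other node the maximum over in-edges
    of the source's aligned position plus the label length.  Linear in the
    number of edges since nodes are processed in coordinate order.
    """
    alt_by_target: dict[int, list[Edge]] = {}
    for e in graph.alt_edges:
        alt_by_target.setdefault(e.target, []).append(e)
    aligned = {graph.nodes[0]: 1}
    for q, r in zip(graph.nodes, graph.nodes[1:]):
        e = graph.ref_edges[q]
        best = aligned[q] + len(e.label)
        for a in alt_by_target.get(r, ()):
            best = max(best, aligned[a.source] + len(a.label))
        aligned[r] = best
    graph.aligned_pos = aligned
    return aligned


def haplotype_path(
    graph: VariantGraph,
    variants: list[VariantRecordLite],
    label: str,
    drop_overlaps: bool = False,
) -> list[Edge]:
    """Edge path from node 1 to node R+1 for one haplotype.

    ``label == REFERENCE_LABEL`` yields the pure reference-edge path.
    Overlapping chosen variants raise :class:`OverlappingVariantError`
    unless ``drop_overlaps`` is set, in which case the later-starting
    record is dropped with a warning.
    """
    chosen: list[tuple[VariantRecordLite, str]] = []
    if label != REFERENCE_LABEL:
        for v in sorted(variants, key=lambda v: (v.pos, v.end, v.alt_alleles)):
            idx = v.genotypes.get(label, 0)
            if idx > 0:
                chosen.append((v, v.alt_alleles[idx - 1]))

    path: list[Edge] = []
    node = 1
    prev: VariantRecordLite | None = None
    for v, alt in chosen:
        if v.pos < node:
            assert prev is not None
            if drop_overlaps:
                warnings.warn(
                    f"haplotype {label}: dropping variant {v.label} overlapping "
                    f"{prev.label}",
                    stacklevel=2,
                )
                continue
            raise OverlappingVariantError(
                f"haplotype {label}: variants {prev.label} and {v.label} overlap"
            )
        while node < v.pos:
            e = graph.ref_edges[node]
            path.append(e)
            node = e.target
        path.append(graph.alt_edge(v.pos, v.end, alt))
        node = v.end
        prev = v
    while node < graph.R + 1:
        e = graph.ref_edges[node]
        path.append(e)
        node = e.target
    return path


def haplotype_sequence(
    graph: VariantGraph,
    variants: list[VariantRecordLite],
    label: str,
    drop_overlaps: bool = False,
) -> str:
    """Ungapped haplotype sequence: concatenated labels along its path."""
    return "".join(
        e.label for e in haplotype_path(graph, variants, label, drop_overlaps)
    )


def gapped_row(graph: VariantGraph, path: list[Edge]) -> str:
    """Apply the gap-fill rule along an edge path.

    After each edge (q, r, label) the row is padded with
    ``aligned_pos(r) - aligned_pos(q) - len(label)`` gap characters.
    """
    if not graph.aligned_pos:
        aligned_positions(graph)
    parts: list[str] = []
    for e in path:
        fill = graph.aligned_pos[e.target] - graph.aligned_pos[e.source] - len(e.label)
        parts.append(e.label + GAP * fill)
    return "".join(parts)


def emit_msa(
    graph: VariantGraph,
    variants: list[VariantRecordLite],
    haplotype_labels: list[str],
    include_reference: bool = True,
    drop_overlaps: bool = False,
) -> ReferenceGuidedMSA:
    """Reference-guided MSA of the requested haplotypes."""
    labels = ([REFERENCE_LABEL] if include_reference else []) + list(haplotype_labels)
    rows = [
        gapped_row(graph, haplotype_path(graph, variants, lab, drop_overlaps))
        for lab in labels
    ]
    return ReferenceGuidedMSA(labels, rows)


def _haplotype_labels(sample: str, ploidy: int) -> list[str]:
    if ploidy == 1:
        return [sample]
    return [f"{sample}_{i + 1}" for i in range(ploidy)]


def read_vcf_haplotypes(
    vcf_path: str,
    chromosome: str,
    reference_fasta: str,
    strict_phasing: bool = True,
) -> tuple[str, list[VariantRecordLite], list[str]]:
    """Read phased variants for one chromosome.

    Returns the reference sequence, one :class:`VariantRecordLite` per VCF
    data line on the chromosome, and the ordered haplotype labels (one per
    sample chromosome copy).  In strict mode an unphased multi-copy
    genotype is an error; in lenient mode ``/`` is treated as phased with
    a warning.
    """
    with pysam.FastaFile(reference_fasta) as fa:
        if chromosome not in fa.references:
            raise FounderPanError(
                f"chromosome {chromosome!r} not present in {reference_fasta}"
            )
        reference = fa.fetch(chromosome).upper()

    variants: list[VariantRecordLite] = []
    hap_labels: list[str] = []
    with pysam.VariantFile(vcf_path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.chrom != chromosome:
                continue
            if rec.alts is None:
                warnings.warn(f"record at {rec.pos} has no ALT; skipped", stacklevel=2)
                continue
            for alt in rec.alts:
                if alt is None or not set(alt.upper()) <= _ALPHABET:
                    raise UnsupportedAlleleError(
                        f"record at {rec.pos}: unsupported allele {alt!r}"
                    )
            genotypes: dict[str, int] = {}
            labels_here: list[str] = []
            for sample in samples:
                call = rec.samples[sample]
                gt = call.get("GT", (None,))
                if gt is None:
                    gt = (None,)
                if len(gt) > 1 and not call.phased:
                    if strict_phasing:
                        raise UnphasedGenotypeError(
                            f"sample {sample} unphased at {rec.chrom}:{rec.pos} "
                            f"(record {rec.id or rec.pos})"
                        )
                    warnings.warn(
                        f"sample {sample} at {rec.chrom}:{rec.pos}: '/' treated "
                        "as phased (lenient mode)",
                        stacklevel=2,
                    )
                for lab, allele in zip(_haplotype_labels(sample, len(gt)), gt):
                    if allele is None:
                        warnings.warn(
                            f"missing allele for {lab} at {rec.pos}; treated as "
                            "reference",
                            stacklevel=2,
                        )
                        allele = 0
                    genotypes[lab] = allele
                    labels_here.append(lab)
            if not hap_labels:
                hap_labels = labels_here
            variants.append(
                VariantRecordLite(
                    pos=rec.pos,
                    ref_allele=rec.ref.upper(),
                    alt_alleles=tuple(a.upper() for a in rec.alts),
                    genotypes=genotypes,
                    id=rec.id,
                )
            )
    if not hap_labels:
        hap_labels = samples
    for v in variants:
        _check_variant(reference, v)
    return reference, variants, hap_labels


def write_node_table(graph: VariantGraph, path: str) -> None:
    """Tab-separated (node, aligned position) sidecar for debugging."""
    if not graph.aligned_pos:
        aligned_positions(graph)
    with open(path, "w") as fh:
        fh.write("node\taligned_pos\n")
        for node in graph.nodes:
            fh.write(f"{node}\t{graph.aligned_pos[node]}\n")
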