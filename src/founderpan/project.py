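"""Projection of ad-hoc-reference variant calls to original coordinates.

The ad hoc reference may embed founder variants, so positions and REF
alleles of records called against it must be rewritten.  Each called
record's ad hoc interval is lifted to MSA columns through the
:class:`~founderpan.adhoc.AdHocMap`; the original reference characters
across those columns become the new REF (a record with no reference
image — a pure insertion — is anchored to the preceding reference base,
VCF-style), while ALT alleles and genotypes are kept as called.

Differences between the ad hoc reference and the original reference
("embedded variants") are reported as well: where no caller record
overlaps, the difference is supported by the reads in every chromosome
copy; where one does, the caller record's non-zero genotype values are
subtracted from the ploidy and the remainder becomes the embedded
record's non-zero genotype count.  All emitted records are left-aligned
and trimmed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam

from .adhoc import AdHocMap
from .errors import FounderPanError
from .msa_graph import GAP


@dataclass
class CalledRecord:
    """A variant record as read from the caller's VCF (1-based pos)."""

    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, tuple[int | None, ...]]
    id: str | None = None


@dataclass
class ProjectedRecord:
    """A record in original-reference coordinates.

    ``origin`` is ``"caller"`` for projected caller records and
    ``"embedded"`` for ad-hoc/reference differences; ``overlapped``
    flags embedded records whose locus also carries a caller record.
    """

    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, tuple[int, ...]]
    origin: str
    id: str | None = None
    overlapped: bool = False

    @property
    def end(self) -> int:
        """Inclusive end position on the reference."""
        return self.pos + len(self.ref) - 1


def normalize_variant(
    pos: int, ref: str, alts: tuple[str, ...], reference: str
) -> tuple[int, str, tuple[str, ...]]:
    """Left-align and trim a variant (VCF normalization convention)."""
    alleles = [ref, *alts]
    while True:
        if all(a for a in alleles) and len({a[-1] for a in alleles}) == 1:
            if any(len(a) == 1 for a in alleles):
                if pos == 1:
                    break
                pos -= 1
                base = reference[pos - 1]
                alleles = [base + a[:-1] for a in alleles]
            else:
                alleles = [a[:-1] for a in alleles]
        else:
            break
    while all(len(a) >= 2 for a in alleles) and len({a[0] for a in alleles}) == 1:
        alleles = [a[1:] for a in alleles]
        pos += 1
    return pos, alleles[0], tuple(alleles[1:])


def _anchor(
    amap: AdHocMap, c1: int, ref_str: str, alts: tuple[str, ...]
) -> tuple[int, str, tuple[str, ...]]:
    """Anchor an allele pair with no reference image to a flanking base."""
    for c in range(c1 - 1, 0, -1):
        if amap.ref_row[c - 1] != GAP:
            base = amap.ref_row[c - 1]
            return int(amap.col_to_ref[c - 1]), base + ref_str, tuple(
                base + a for a in alts
            )
    # no base to the left: anchor to the following one
    for c in range(c1, amap.n + 1):
        if amap.ref_row[c - 1] != GAP:
            base = amap.ref_row[c - 1]
            return int(amap.col_to_ref[c - 1]), ref_str + base, tuple(
                a + base for a in alts
            )
    raise FounderPanError("reference row contains no bases; cannot anchor record")


def project_record(
    record: CalledRecord, amap: AdHocMap, reference: str
) -> ProjectedRecord:
    """Rewrite one caller record into original-reference coordinates."""
    if not 1 <= record.pos <= len(amap.adhoc):
        raise FounderPanError(
            f"record at ad hoc position {record.pos} outside ad hoc reference"
        )
    if amap.adhoc[record.pos - 1 : record.pos - 1 + len(record.ref)] != record.ref:
        raise FounderPanError(
            f"record at {record.pos}: REF {record.ref!r} does not match the "
            "ad hoc reference"
        )
    c1 = amap.adhoc_to_msa_col(record.pos)
    c2 = amap.adhoc_to_msa_col(record.pos + len(record.ref) - 1)
    ref_cols = [c for c in range(c1, c2 + 1) if amap.ref_row[c - 1] != GAP]
    if ref_cols:
        pos = int(amap.col_to_ref[ref_cols[0] - 1])
        ref_str = "".join(amap.ref_row[c - 1] for c in ref_cols)
        alts = record.alts
    else:
        pos, ref_str, alts = _anchor(amap, c1, "", record.alts)
    pos, ref_str, alts = normalize_variant(pos, ref_str, alts, reference)
    genotypes = {
        s: tuple(0 if g is None else g for g in gt)
        for s, gt in record.genotypes.items()
    }
    return ProjectedRecord(pos, ref_str, alts, genotypes, "caller", record.id)


def _diff_runs(amap: AdHocMap) -> list[tuple[int, int]]:
    """Maximal runs of MSA columns where the ad hoc row differs from the
    reference row (inclusive 1-based column intervals)."""
    a = np.frombuffer(amap.adhoc_row.encode("ascii"), dtype=np.uint8)
    r = np.frombuffer(amap.ref_row.encode("ascii"), dtype=np.uint8)
    diff = a != r
    runs: list[tuple[int, int]] = []
    start = None
    for c in range(len(diff)):
        if diff[c] and start is None:
            start = c
        elif not diff[c] and start is not None:
            runs.append((start + 1, c))
            start = None
    if start is not None:
        runs.append((start + 1, len(diff)))
    return runs


def emit_embedded_variants(
    amap: AdHocMap,
    caller_records: list[ProjectedRecord],
    ploidy: int,
    samples: list[str],
    reference: str,
) -> list[ProjectedRecord]:
    """Ad-hoc/reference differences with ploidy-aware genotypes.

    With no overlapping caller record the difference is carried by every
    chromosome copy; otherwise the caller's non-zero genotype count is
    subtracted from the ploidy.  A difference whose remaining copy count
    is zero for all samples is suppressed.
    """
    out: list[ProjectedRecord] = []
    for cs, ce in _diff_runs(amap):
        ref_str = "".join(
            amap.ref_row[c - 1] for c in range(cs, ce + 1) if amap.ref_row[c - 1] != GAP
        )
        alt_str = "".join(
            amap.adhoc_row[c - 1]
            for c in range(cs, ce + 1)
            if amap.adhoc_row[c - 1] != GAP
        )
        if ref_str and alt_str:
            pos = int(amap.col_to_ref[next(
                c for c in range(cs, ce + 1) if amap.ref_row[c - 1] != GAP
            ) - 1])
        elif ref_str:
            # founder deletion: borrow the preceding shared reference base
            pos, ref_str, alts = _anchor_deletion(amap, cs, ref_str)
            alt_str = alts[0]
        else:
            # founder insertion: anchor to a flanking reference base
            pos, ref_str, alts = _anchor(amap, cs, ref_str, (alt_str,))
            alt_str = alts[0]
        pos, ref_str, alts = normalize_variant(pos, ref_str, (alt_str,), reference)
        if ref_str == alts[0]:
            continue
        end = pos + len(ref_str) - 1
        genotypes: dict[str, tuple[int, ...]] = {}
        overlapped = False
        for s in samples:
            covered = 0
            for rec in caller_records:
                if rec.pos <= end and rec.end >= pos:
                    gt = rec.genotypes.get(s, ())
                    covered += sum(1 for g in gt if g)
                    overlapped = True
            k = max(ploidy - min(covered, ploidy), 0)
            genotypes[s] = (0,) * (ploidy - k) + (1,) * k
        if any(any(g for g in gt) for gt in genotypes.values()):
            out.append(
                ProjectedRecord(
                    pos, ref_str, alts, genotypes, "embedded", None, overlapped
                )
            )
    return out


def _anchor_deletion(
    amap: AdHocMap, cs: int, ref_str: str
) -> tuple[int, str, tuple[str, ...]]:
    for c in range(cs - 1, 0, -1):
        if amap.ref_row[c - 1] != GAP and amap.adhoc_row[c - 1] != GAP:
            base = amap.ref_row[c - 1]
            return int(amap.col_to_ref[c - 1]), base + ref_str, (base,)
    raise FounderPanError("deletion at the start of the reference cannot be anchored")


def read_called_vcf(path: str) -> tuple[list[CalledRecord], list[str]]:
    records: list[CalledRecord] = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None:
                continue
            genotypes = {
                s: tuple(rec.samples[s].get("GT", (None,)) or (None,))
                for s in samples
            }
            records.append(
                CalledRecord(
                    pos=rec.pos,
                    ref=rec.ref.upper(),
                    alts=tuple(a.upper() for a in rec.alts),
                    genotypes=genotypes,
                    id=rec.id,
                )
            )
    return records, samples


def write_projected_vcf(
    records: list[ProjectedRecord],
    samples: list[str],
    reference: str,
    chrom: str,
    path: str,
) -> None:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={len(reference)}>")
    header.add_line(
        '##INFO=<ID=ORIGIN,Number=1,Type=String,'
        'Description="caller: projected caller record; embedded: ad hoc '
        'reference difference">'
    )
    header.add_line(
        '##INFO=<ID=ADHOC_OVERLAP,Number=0,Type=Flag,'
        'Description="Embedded difference overlapping a caller record">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.pos, r.ref, r.alts)):
            vrec = out.new_record(
                contig=chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, *rec.alts),
                id=rec.id,
            )
            vrec.info["ORIGIN"] = rec.origin
            if rec.overlapped:
                vrec.info["ADHOC_OVERLAP"] = True
            for s in samples:
                gt = rec.genotypes.get(s)
                if gt is None:
                    gt = (0,) * len(next(iter(rec.genotypes.values()), (0,)))
                vrec.samples[s]["GT"] = gt
                vrec.samples[s].phased = False
            out.write(vrec)


def project_vcf(
    calls_path: str | None,
    amap: AdHocMap,
    reference: str,
    ploidy: int,
    out_path: str,
    chrom: str = "ref",
    default_sample: str = "SAMPLE",
) -> list[ProjectedRecord]:
    """File-level wrapper: project caller records, add embedded records,
    sort, validate REF against the reference and write a VCF."""
    reference = reference.upper()
    if calls_path is not None:
        called, samples = read_called_vcf(calls_path)
    else:
        called, samples = [], []
    if not samples:
        samples = [default_sample]
    projected = [project_record(rec, amap, reference) for rec in called]
    if any(r1.pos > r2.pos for r1, r2 in zip(projected, projected[1:])):
        warnings.warn("input records out of order; output sorted internally",
                      stacklevel=2)
    embedded = emit_embedded_variants(amap, projected, ploidy, samples, reference)
    records = projected + embedded
    for rec in records:
        expected = reference[rec.pos - 1 : rec.pos - 1 + len(rec.ref)]
        if rec.ref != expected:
            raise FounderPanError(
                f"projected REF {rec.ref!r} at {rec.pos} does not match the "
                f"reference ({expected!r})"
            )
    write_projected_vcf(records, samples, reference, chrom, out_path)
    return sorted(records, key=lambda r: (r.pos, r.ref, r.alts))
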