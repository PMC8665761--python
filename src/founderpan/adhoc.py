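"""Support accumulation and heaviest-path ad hoc reference extraction.

Given best read alignments against the (ungapped) founder sequences —
directly or via the kernel provenance map — each alignment increments a
contiguous column range of an m x n support matrix, m being the indexed
rows (original reference as row 0) and n the founder MSA width.  The
ad hoc reference then follows the *heaviest path*: per MSA column the
character of the row with maximal support is appended, gaps appending
nothing.  Ties go to the lowest row index, so with zero support the
ad hoc reference is the original reference.  The per-column choices
induce a three-way coordinate map between ad hoc positions, MSA columns
and original reference positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam

from .errors import FounderPanError
from .kernel import KernelIndexMap
from .msa_graph import GAP, ReferenceGuidedMSA


@dataclass
class SupportMatrix:
    """m x n per-row, per-column best-alignment coverage counts."""

    labels: list[str]
    M: np.ndarray

    @property
    def m(self) -> int:
        return self.M.shape[0]

    @property
    def n(self) -> int:
        return self.M.shape[1]


@dataclass
class AdHocMap:
    """Heaviest-path output and its coordinate maps.

    ``ref_row`` and ``adhoc_row`` are gapped strings of width n: the
    original reference row of the MSA and the per-column chosen
    characters.  Derived arrays (0 marks "no image"): per column the
    1-based ad hoc position and original reference position, and their
    inverses.
    """

    chosen: np.ndarray
    ref_row: str
    adhoc_row: str
    adhoc: str = field(init=False)
    col_to_adhoc: np.ndarray = field(init=False)
    col_to_ref: np.ndarray = field(init=False)
    adhoc_to_col: np.ndarray = field(init=False)
    ref_to_col: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.adhoc = self.adhoc_row.replace(GAP, "")
        adhoc_arr = np.frombuffer(self.adhoc_row.encode("ascii"), dtype=np.uint8)
        ref_arr = np.frombuffer(self.ref_row.encode("ascii"), dtype=np.uint8)
        gap = ord(GAP)
        self.col_to_adhoc = np.where(
            adhoc_arr != gap, np.cumsum(adhoc_arr != gap), 0
        ).astype(np.int64)
        self.col_to_ref = np.where(
            ref_arr != gap, np.cumsum(ref_arr != gap), 0
        ).astype(np.int64)
        self.adhoc_to_col = np.flatnonzero(adhoc_arr != gap) + 1
        self.ref_to_col = np.flatnonzero(ref_arr != gap) + 1

    @property
    def n(self) -> int:
        return len(self.ref_row)

    def adhoc_to_msa_col(self, position: int) -> int:
        """MSA column (1-based) of an ad hoc position."""
        if not 1 <= position <= len(self.adhoc):
            raise FounderPanError(f"ad hoc position {position} out of range")
        return int(self.adhoc_to_col[position - 1])

    def ref_to_msa_col(self, position: int) -> int:
        if not 1 <= position <= len(self.ref_to_col):
            raise FounderPanError(f"reference position {position} out of range")
        return int(self.ref_to_col[position - 1])

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("column\tchosen_row\tref_char\tadhoc_char\tref_pos\tadhoc_pos\n")
            for c in range(self.n):
                fh.write(
                    f"{c + 1}\t{int(self.chosen[c])}\t{self.ref_row[c]}\t"
                    f"{self.adhoc_row[c]}\t{int(self.col_to_ref[c])}\t"
                    f"{int(self.col_to_adhoc[c])}\n"
                )

    @classmethod
    def read_tsv(cls, path: str) -> "AdHocMap":
        chosen: list[int] = []
        ref_chars: list[str] = []
        adhoc_chars: list[str] = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("column"):
                raise FounderPanError(f"{path}: not an ad hoc map file")
            for line in fh:
                _, row, ref_c, adhoc_c, _, _ = line.rstrip("\n").split("\t")
                chosen.append(int(row))
                ref_chars.append(ref_c)
                adhoc_chars.append(adhoc_c)
        return cls(np.array(chosen), "".join(ref_chars), "".join(adhoc_chars))


def founder_to_msa_column(msa: ReferenceGuidedMSA, row: int, position: int) -> int:
    """MSA column of the ``position``-th non-gap character of a row."""
    return msa.column_of(row, position)


def msa_column_to_founder(msa: ReferenceGuidedMSA, row: int, column: int) -> int | None:
    """Inverse lift; None when the row holds a gap at the column."""
    return msa.position_of(row, column)


def _best_alignments(alignment_path: str):
    """One best record per read: primary mapped records ranked by
    alignment score, then mapping quality, then input order."""
    best: dict[tuple[str, int], tuple[tuple[float, int, int], object]] = {}
    with pysam.AlignmentFile(alignment_path, check_sq=False) as af:
        for order, rec in enumerate(af):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            mate = 1 if rec.is_read1 else (2 if rec.is_read2 else 0)
            key = (rec.query_name, mate)
            score = rec.get_tag("AS") if rec.has_tag("AS") else float("-inf")
            rank = (-float(score), -rec.mapping_quality, order)
            if key not in best or rank < best[key][0]:
                best[key] = (
                    rank,
                    (rec.reference_name, rec.reference_start, rec.reference_end),
                )
    return [v[1] for v in best.values()]


def accumulate_support(
    alignment_path: str,
    msa: ReferenceGuidedMSA,
    kernel_map: KernelIndexMap | None = None,
) -> SupportMatrix:
    """Build the support matrix from best alignments.

    Alignments name either founder MSA rows directly or kernel pieces
    (``kernel_map`` given), whose provenance lifts the span onto founder
    coordinates.  The spanned founder positions are converted to an
    inclusive MSA column range (interior gap columns included) and that
    range of the row is incremented.
    """
    M = np.zeros((len(msa.labels), msa.width), dtype=np.int64)
    row_of = {lab: i for i, lab in enumerate(msa.labels)}
    piece_of = (
        {p.piece_id: p for p in kernel_map.pieces} if kernel_map is not None else {}
    )
    for name, start0, end0 in _best_alignments(alignment_path):
        if kernel_map is not None and name in piece_of:
            piece = piece_of[name]
            row = row_of.get(kernel_map.names[piece.seq])
            if row is None:
                raise FounderPanError(
                    f"kernel piece {name} maps to unknown founder "
                    f"{kernel_map.names[piece.seq]}"
                )
            p = piece.start + start0
            q = piece.start + end0 - 1
        elif name in row_of:
            row = row_of[name]
            p = start0 + 1
            q = end0
        else:
            raise FounderPanError(f"alignment to unknown sequence {name!r}")
        if q < p:
            warnings.warn(f"zero-length alignment span on {name}; ignored",
                          stacklevel=2)
            continue
        c1 = msa.column_of(row, p)
        c2 = msa.column_of(row, q)
        M[row, c1 - 1 : c2] += 1
    return SupportMatrix(list(msa.labels), M)


def heaviest_path(support: SupportMatrix, msa: ReferenceGuidedMSA) -> AdHocMap:
    """Per-column argmax extraction of the ad hoc reference.

    Ties break to the lowest row index; with the original reference as
    row 0 this makes zero coverage reproduce the reference exactly.
    """
    if support.M.shape != (len(msa.labels), msa.width):
        raise FounderPanError(
            f"support matrix {support.M.shape} does not match MSA "
            f"({len(msa.labels)}, {msa.width})"
        )
    chosen = support.M.argmax(axis=0)
    adhoc_row = "".join(msa.rows[r][c] for c, r in enumerate(chosen))
    return AdHocMap(chosen=chosen, ref_row=msa.rows[0], adhoc_row=adhoc_row)


def write_adhoc_fasta(amap: AdHocMap, path: str, name: str = "adhoc") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        seq = amap.adhoc
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
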