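"""LZ kernel construction for hybrid read-alignment indexing.

The founder sequences are factorized left to right into *literal*
phrases (first occurrences) and *copying* phrases (subsequences with an
earlier, non-overlapping occurrence in the concatenation).  For reads of
length ``P``, the middle of any copying phrase longer than ``2P`` can
never be the unique home of a read: every window of length <= P that
overlaps the middle lies entirely inside the phrase and therefore also
occurs at the phrase's source.  The *kernel* hence keeps literal phrases
and short copies whole but excises the middle of long copies, keeping
only their first and last ``P`` characters as detached pieces.  A
provenance map from kernel pieces back to founder coordinates lets
alignments against the kernel be lifted onto the founders.

The parse dialect is a greedy longest-previous-factor with sources
required to end at or before the phrase start (no self-overlap) and
phrases never crossing sequence boundaries.  The operative contract is
the P-mer coverage property: every substring of length <= P of every
input occurs in some kernel piece; a post-hoc verifier retains a phrase
whole if its excision would break the property (possible when the
phrase's source region was itself excised).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import FounderPanError

_SEP = "\x01"


@dataclass(frozen=True)
class LZPhrase:
    """One phrase of the parse.

    Coordinates are 0-based offsets within the named sequences; the
    phrase covers ``[start, start + length)`` of sequence ``seq``.  Copy
    phrases carry the (strictly earlier, non-overlapping) source
    interval start.
    """

    kind: str  # "literal" | "copy"
    seq: int
    start: int
    length: int
    src_seq: int | None = None
    src_start: int | None = None
    text: str | None = None  # literal phrases carry their characters


@dataclass(frozen=True)
class KernelPiece:
    """A retained kernel piece with its founder provenance (1-based start)."""

    piece_id: str
    text: str
    seq: int
    start: int
    length: int


@dataclass
class KernelIndexMap:
    """Ordered kernel pieces plus the piece -> founder coordinate map."""

    P: int
    names: list[str]
    pieces: list[KernelPiece]

    @property
    def total_length(self) -> int:
        return sum(p.length for p in self.pieces)

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for p in self.pieces:
                fh.write(f">{p.piece_id} {self.names[p.seq]}:{p.start}:{p.length}\n")
                fh.write(p.text + "\n")

    def write_map(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("piece_id\tfounder\tstart\tlength\n")
            for p in self.pieces:
                fh.write(f"{p.piece_id}\t{self.names[p.seq]}\t{p.start}\t{p.length}\n")

    @classmethod
    def read_map(cls, path: str, P: int = 0) -> "KernelIndexMap":
        """Rebuild provenance (piece texts absent) from the TSV sidecar."""
        names: list[str] = []
        pieces: list[KernelPiece] = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("piece_id"):
                raise FounderPanError(f"{path}: not a kernel map file")
            for line in fh:
                pid, founder, start, length = line.rstrip("\n").split("\t")
                if founder not in names:
                    names.append(founder)
                pieces.append(
                    KernelPiece(pid, "", names.index(founder), int(start), int(length))
                )
        return cls(P, names, pieces)


def lz_parse(sequences: list[str]) -> list[LZPhrase]:
    """Greedy longest-previous-factor parse of the concatenation.

    At each position the longest substring with a complete occurrence
    strictly earlier in the (separator-protected) concatenation is
    emitted as a copy phrase; otherwise a single literal character, with
    adjacent literals merged into runs.
    """
    text = _SEP.join(sequences)
    starts: list[int] = []
    off = 0
    for s in sequences:
        starts.append(off)
        off += len(s) + 1

    phrases: list[LZPhrase] = []

    def global_to_local(g: int) -> tuple[int, int]:
        for si in range(len(sequences) - 1, -1, -1):
            if g >= starts[si]:
                return si, g - starts[si]
        raise AssertionError

    for si, seq in enumerate(sequences):
        i = 0
        base = starts[si]
        while i < len(seq):
            g = base + i
            lo, hi = 1, len(seq) - i
            if text.find(text[g : g + 1], 0, g) < 0:
                # literal character; merge with a preceding literal run
                last = phrases[-1] if phrases else None
                if (
                    last is not None
                    and last.kind == "literal"
                    and last.seq == si
                    and last.start + last.length == i
                ):
                    phrases[-1] = LZPhrase(
                        "literal", si, last.start, last.length + 1,
                        text=last.text + seq[i],
                    )
                else:
                    phrases.append(LZPhrase("literal", si, i, 1, text=seq[i]))
                i += 1
                continue
            # longest l with a full occurrence inside [0, g); monotone in l
            while lo < hi:
                mid = (lo + hi + 1) // 2
                if text.find(text[g : g + mid], 0, g) >= 0:
                    lo = mid
                else:
                    hi = mid - 1
            src = text.find(text[g : g + lo], 0, g)
            src_seq, src_off = global_to_local(src)
            phrases.append(LZPhrase("copy", si, i, lo, src_seq, src_off))
            i += lo
    return phrases


def decode_parse(phrases: list[LZPhrase]) -> list[str]:
    """Reconstruct the input sequences from a parse (losslessness check).

    Literal phrases carry their own text; copy phrases are resolved from
    the already-decoded earlier part of the concatenation.
    """
    out: list[list[str]] = []
    for ph in phrases:
        while len(out) <= ph.seq:
            out.append([])
        if ph.kind == "literal":
            out[ph.seq].append(ph.text)
        else:
            src_text = "".join(out[ph.src_seq])
            out[ph.seq].append(src_text[ph.src_start : ph.src_start + ph.length])
    return ["".join(parts) for parts in out]


def _build_pieces(
    sequences: list[str],
    names: list[str],
    phrases: list[LZPhrase],
    P: int,
    retain_whole: set[int],
) -> list[KernelPiece]:
    pieces: list[KernelPiece] = []
    runs: list[tuple[int, int, int]] = []  # (seq, start, end) 0-based half-open
    cur: tuple[int, int, int] | None = None

    def flush() -> None:
        nonlocal cur
        if cur is not None and cur[2] > cur[1]:
            runs.append(cur)
        cur = None

    for idx, ph in enumerate(phrases):
        if cur is not None and cur[0] != ph.seq:
            flush()
        excise = ph.kind == "copy" and ph.length > 2 * P and idx not in retain_whole
        if not excise:
            if cur is None:
                cur = (ph.seq, ph.start, ph.start + ph.length)
            else:
                cur = (cur[0], cur[1], ph.start + ph.length)
        else:
            if cur is None:
                cur = (ph.seq, ph.start, ph.start + P)
            else:
                cur = (cur[0], cur[1], ph.start + P)
            flush()
            cur = (ph.seq, ph.start + ph.length - P, ph.start + ph.length)
    flush()

    for i, (si, a, b) in enumerate(runs):
        pieces.append(
            KernelPiece(f"piece{i}", sequences[si][a:b], si, a + 1, b - a)
        )
    return pieces


def _coverage_gap(
    sequences: list[str], pieces: list[KernelPiece], P: int
) -> tuple[int, int] | None:
    """First (seq, position) whose min(P, len)-mer is in no piece, or None."""
    by_k: dict[int, set[str]] = {}
    for si, seq in enumerate(sequences):
        k = min(P, len(seq))
        if k == 0:
            continue
        if k not in by_k:
            kmers: set[str] = set()
            for p in pieces:
                for j in range(len(p.text) - k + 1):
                    kmers.add(p.text[j : j + k])
            by_k[k] = kmers
        kmers = by_k[k]
        for j in range(len(seq) - k + 1):
            if seq[j : j + k] not in kmers:
                return si, j
    return None


def build_kernel(
    sequences: list[str],
    P: int,
    names: list[str] | None = None,
    parse: list[LZPhrase] | None = None,
) -> KernelIndexMap:
    """Kernel pieces with the 2P excision rule and provenance map.

    Literal phrases and copies of length <= 2P are retained whole;
    longer copies contribute their first and last P characters as
    detached pieces (contiguous retained runs merged).  A post-hoc
    verifier re-retains whole any excised phrase whose removal breaks
    P-mer coverage.
    """
    if P < 1:
        raise FounderPanError("P must be >= 1")
    if names is None:
        names = [f"seq{i}" for i in range(len(sequences))]
    sequences = [s.upper() for s in sequences]
    if parse is None:
        parse = lz_parse(sequences)

    retain_whole: set[int] = set()
    excisable = [
        i for i, ph in enumerate(parse) if ph.kind == "copy" and ph.length > 2 * P
    ]
    while True:
        pieces = _build_pieces(sequences, names, parse, P, retain_whole)
        gap = _coverage_gap(sequences, pieces, P)
        if gap is None:
            return KernelIndexMap(P, list(names), pieces)
        gi, gj = gap
        k = min(P, len(sequences[gi]))
        culprit = None
        for idx in excisable:
            if idx in retain_whole:
                continue
            ph = parse[idx]
            if ph.seq == gi and ph.start < gj + k and ph.start + ph.length > gj:
                culprit = idx
                break
        if culprit is None:
            raise FounderPanError(
                f"P-mer coverage gap at sequence {gi} offset {gj} not attributable "
                "to an excised phrase"
            )
        retain_whole.add(culprit)


def lift_kernel_position(
    kmap: KernelIndexMap, piece_index: int, offset: int
) -> tuple[int, int]:
    """Founder (sequence index, 1-based position) under a kernel piece offset."""
    piece = kmap.pieces[piece_index]
    if not 0 <= offset < piece.length:
        raise FounderPanError(
            f"offset {offset} outside piece {piece.piece_id} of length {piece.length}"
        )
    return piece.seq, piece.start + offset
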