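"""Founder sequence reconstruction by bridge-based segmentation.

A *bridge* of the variant graph is a reference edge traversed by every
source-to-sink path; equivalently, a reference edge not spanned by any
alternative edge.  Cutting the graph at bridge nodes partitions the
reference into segments; within a segment each haplotype restricts to a
short subsequence, and only the number of *distinct* subsequences per
segment matters for how many founder sequences are needed.

The segmentation is chosen by dynamic programming: minimize, over all
cut subsets whose segments all span at least ``L`` reference positions,
the maximum per-segment distinct-subsequence count.  Ties prefer the
most recently cut (rightmost) final segment, applied recursively.  The
per-segment subsequences are then joined left to right into ``f``
founder slots by a greedy bipartite matching that keeps the most common
local haplotype combinations contiguous.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field

from .errors import FounderPanError
from .msa_graph import (
    GAP,
    REFERENCE_LABEL,
    Edge,
    ReferenceGuidedMSA,
    VariantGraph,
    VariantRecordLite,
    aligned_positions,
    gapped_row,
    haplotype_path,
)

N_FILL = "N"


@dataclass
class BridgeSet:
    """Bridge edges and the ordered set Q of their endpoint nodes."""

    bridges: list[tuple[int, int]]
    Q: list[int]

    def interior(self, R: int) -> list[int]:
        """Bridge nodes usable as cut positions (boundaries excluded)."""
        return [q for q in self.Q if 1 < q < R + 1]


@dataclass
class Segmentation:
    """Chosen cuts and the minimized objective.

    ``segments`` are half-open node-coordinate intervals partitioning
    ``[1, R + 1)``; a segment's size is the difference of its reference
    positions.
    """

    L: int
    cuts: list[int]
    segments: list[tuple[int, int]]
    D_value: int
    d_per_segment: list[int]

    @property
    def sizes(self) -> list[int]:
        return [b - a for a, b in self.segments]


@dataclass
class SegmentPathTable:
    """Distinct per-segment subsequences with occurrence counts.

    Occurrences are tallied over the input haplotype paths plus the
    reference path (weight 1).  ``representatives`` keeps one edge path
    per distinct subsequence for later gapped emission; ``by_haplotype``
    records, for every input path, its subsequence in each segment.
    """

    segments: list[tuple[int, int]]
    counts: list[Counter]
    representatives: list[dict[str, tuple[Edge, ...]]]
    by_haplotype: dict[str, list[str]]

    @property
    def max_distinct(self) -> int:
        return max(len(c) for c in self.counts)

    def sorted_distinct(self, k: int) -> list[str]:
        """Segment k's subsequences, descending count, ties lexicographic."""
        return sorted(self.counts[k], key=lambda s: (-self.counts[k][s], s))


@dataclass
class FounderSet:
    """Per-segment slot assignments and the join chains.

    ``slots[k][i]`` is the subsequence assigned to founder slot ``i`` in
    segment ``k`` (None = still available, i.e. fill material);
    ``chains[i]`` lists the slot index followed by founder ``i`` in each
    segment.
    """

    f: int
    segmentation: Segmentation
    slots: list[list[str | None]]
    matchings: list[dict[int, int]]
    chains: list[list[int]]
    fill: str


def find_bridge_nodes(graph: VariantGraph) -> BridgeSet:
    """Reference edges lying on every source-to-sink path.

    A reference edge (q, r) is a bridge iff no alternative edge (a, b)
    spans it, i.e. none with a < r and b > q.
    """
    bridges: list[tuple[int, int]] = []
    for q, r in zip(graph.nodes, graph.nodes[1:]):
        spanned = any(e.source < r and e.target > q for e in graph.alt_edges)
        if not spanned:
            bridges.append((q, r))
    Q = sorted({n for br in bridges for n in br})
    return BridgeSet(bridges, Q)


def _restrict(path_nodes: list[int], path: list[Edge], a: int, b: int) -> tuple[Edge, ...]:
    """Edges of ``path`` inside the node interval [a, b)."""
    i = bisect_left(path_nodes, a)
    j = bisect_left(path_nodes, b)
    if i == len(path_nodes) or path_nodes[i] != a:
        raise FounderPanError(f"path does not pass through node {a}")
    if j == len(path_nodes) or path_nodes[j] != b:
        raise FounderPanError(f"path does not pass through node {b}")
    return tuple(path[i:j])


def haplotype_paths(
    graph: VariantGraph,
    variants: list[VariantRecordLite],
    haplotype_labels: list[str],
    include_reference: bool = True,
    drop_overlaps: bool = False,
) -> dict[str, list[Edge]]:
    """Edge paths for the inputs, the reference included as one haplotype."""
    labels = ([REFERENCE_LABEL] if include_reference else []) + list(haplotype_labels)
    return {
        lab: haplotype_path(graph, variants, lab, drop_overlaps) for lab in labels
    }


def distinct_segment_paths(
    paths: dict[str, list[Edge]],
    a: int,
    b: int,
    eligible: set[int] | None = None,
) -> tuple[Counter, dict[str, tuple[Edge, ...]]]:
    """Distinct subsequence -> occurrence count over [a, b).

    Counts restrictions of the input sequences (haplotypes plus
    reference), not combinatorial graph paths.  Also returns one
    representative edge path per distinct subsequence.
    """
    if eligible is not None and not {a, b} <= eligible:
        raise FounderPanError(f"{a} and {b} are not both cut-eligible positions")
    counts: Counter = Counter()
    reps: dict[str, tuple[Edge, ...]] = {}
    for path in paths.values():
        nodes = [e.source for e in path] + [path[-1].target] if path else [1]
        sub_edges = _restrict(nodes, path, a, b)
        seq = "".join(e.label for e in sub_edges)
        counts[seq] += 1
        reps.setdefault(seq, sub_edges)
    return counts, reps


def optimal_segmentation(
    graph: VariantGraph,
    paths: dict[str, list[Edge]],
    L: int,
) -> Segmentation:
    """Minimize the maximum per-segment distinct-subsequence count.

    Dynamic program over bridge nodes: the best value for a prefix
    ending at cut-eligible node r is the minimum, over the no-cut option
    (feasible when r - 1 >= L) and all previous cuts q with r - q >= L,
    of max(best(q), d(q, r)).  Among equal-valued options the rightmost
    last cut wins, recursively; the single uncut segment is the fallback
    when no segmentation satisfies the length constraint.
    """
    if L < 1:
        raise FounderPanError("L must be >= 1")
    R = graph.R
    sink = R + 1
    interior = find_bridge_nodes(graph).interior(R)

    memo: dict[tuple[int, int], int] = {}

    def d(a: int, b: int) -> int:
        key = (a, b)
        if key not in memo:
            memo[key] = len(distinct_segment_paths(paths, a, b)[0])
        return memo[key]

    # best[r] = (D, previous cut or None for the uncut prefix)
    best: dict[int, tuple[int, int | None]] = {}
    for r in interior + [sink]:
        options: list[tuple[int, int]] = []  # (D, q_key); q_key=0 means no cut
        if r - 1 >= L:
            options.append((d(1, r), 0))
        for q in interior:
            if q >= r or r - q < L or q not in best:
                continue
            options.append((max(best[q][0], d(q, r)), q))
        if options:
            val, qk = min(options, key=lambda t: (t[0], -t[1]))
            best[r] = (val, qk if qk else None)

    if sink not in best:  # no feasible segmentation: single-segment fallback
        cuts: list[int] = []
        D = d(1, sink)
    else:
        D = best[sink][0]
        cuts = []
        r = sink
        while True:
            q = best[r][1]
            if q is None:
                break
            cuts.append(q)
            r = q
        cuts.reverse()

    bounds = [1] + cuts + [sink]
    segments = list(zip(bounds, bounds[1:]))
    return Segmentation(L, cuts, segments, D, [d(a, b) for a, b in segments])


def build_segment_tables(
    paths: dict[str, list[Edge]], segmentation: Segmentation
) -> SegmentPathTable:
    counts, reps, by_hap = [], [], {lab: [] for lab in paths}
    for a, b in segmentation.segments:
        c, r = distinct_segment_paths(paths, a, b)
        counts.append(c)
        reps.append(r)
    for lab, path in paths.items():
        nodes = [e.source for e in path] + [path[-1].target] if path else [1]
        for a, b in segmentation.segments:
            sub = "".join(e.label for e in _restrict(nodes, path, a, b))
            by_hap[lab].append(sub)
    return SegmentPathTable(segmentation.segments, counts, reps, by_hap)


def _claim_slot(
    slots: list[str | None], connected: set[int], value: str
) -> int | None:
    """Slot for ``value``: lowest unconnected slot holding it, else the
    lowest unconnected available slot (which is then assigned ``value``)."""
    for i, v in enumerate(slots):
        if v == value and i not in connected:
            return i
    for i, v in enumerate(slots):
        if v is None and i not in connected:
            slots[i] = value
            return i
    return None


def greedy_join(
    table: SegmentPathTable, f: int, fill: str = "dup"
) -> FounderSet:
    """Join per-segment subsequences into f founder slot chains.

    Consecutive segment pairs are processed left to right.  Distinct
    subsequences of the concatenated window, in descending occurrence
    order (ties lexicographic), connect their slots when both sides are
    unconnected; a connected side falls back to an available slot if one
    exists, otherwise the window path is skipped.  Leftover slots are
    paired in ascending index.  Still-available slots are finally filled
    by duplicating distinct subsequences cyclically in descending count
    order (``fill="dup"``, default) or left for N-filling
    (``fill="N"``).
    """
    dmax = table.max_distinct
    if f < dmax:
        raise FounderPanError(
            f"f={f} is below the segmentation bound max d(q, r) = {dmax}"
        )
    if fill not in ("dup", "N"):
        raise FounderPanError(f"unknown fill mode {fill!r}")

    nseg = len(table.segments)
    slots: list[list[str | None]] = []
    for k in range(nseg):
        ordered = table.sorted_distinct(k)
        slots.append(list(ordered) + [None] * (f - len(ordered)))

    matchings: list[dict[int, int]] = []
    for k in range(nseg - 1):
        window: Counter = Counter(
            (subs[k], subs[k + 1]) for subs in table.by_haplotype.values()
        )
        conn_s: set[int] = set()
        conn_t: set[int] = set()
        edges: dict[int, int] = {}
        for (u, v), _ in sorted(window.items(), key=lambda t: (-t[1], t[0])):
            s = _claim_slot(slots[k], conn_s, u)
            if s is None:
                continue
            t = _claim_slot(slots[k + 1], conn_t, v)
            if t is None:
                continue
            conn_s.add(s)
            conn_t.add(t)
            edges[s] = t
        rest_s = [i for i in range(f) if i not in conn_s]
        rest_t = [i for i in range(f) if i not in conn_t]
        for s, t in zip(rest_s, rest_t):
            edges[s] = t
        matchings.append(edges)

    if fill == "dup":
        for k in range(nseg):
            ordered = table.sorted_distinct(k)
            j = 0
            for i in range(f):
                if slots[k][i] is None:
                    slots[k][i] = ordered[j % len(ordered)]
                    j += 1

    chains: list[list[int]] = []
    for i in range(f):
        chain = [i]
        for k in range(nseg - 1):
            chain.append(matchings[k][chain[-1]])
        chains.append(chain)
    return FounderSet(f, _seg_of(table), slots, matchings, chains, fill)


def _seg_of(table: SegmentPathTable) -> Segmentation:
    sizes = [b - a for a, b in table.segments]
    cuts = [a for a, _ in table.segments[1:]]
    return Segmentation(
        L=min(sizes),
        cuts=cuts,
        segments=list(table.segments),
        D_value=table.max_distinct,
        d_per_segment=[len(c) for c in table.counts],
    )


def emit_founders(
    founder_set: FounderSet,
    graph: VariantGraph,
    table: SegmentPathTable,
    include_reference: bool = True,
) -> tuple[ReferenceGuidedMSA, dict[str, str]]:
    """Gapped founder MSA (reference row first) plus ungapped sequences.

    Each segment block is laid out with the same gap-fill rule as the
    haplotype MSA, so founder rows share the full-haplotype MSA width.
    An unfilled (available) slot becomes an all-N block spanning the
    segment's columns.
    """
    if not graph.aligned_pos:
        aligned_positions(graph)
    seg_width = {
        (a, b): graph.aligned_pos[b] - graph.aligned_pos[a]
        for a, b in table.segments
    }
    labels: list[str] = []
    rows: list[str] = []
    if include_reference:
        ref_path = haplotype_path(graph, [], REFERENCE_LABEL)
        labels.append(REFERENCE_LABEL)
        rows.append(gapped_row(graph, ref_path))
    for i, chain in enumerate(founder_set.chains):
        parts: list[str] = []
        for k, seg in enumerate(table.segments):
            sub = founder_set.slots[k][chain[k]]
            if sub is None:
                parts.append(N_FILL * seg_width[seg])
            else:
                parts.append(gapped_row(graph, list(table.representatives[k][sub])))
        labels.append(f"founder{i + 1}")
        rows.append("".join(parts))
    msa = ReferenceGuidedMSA(labels, rows)
    seqs = {
        lab: row.replace(GAP, "")
        for lab, row in zip(labels, rows)
        if lab != REFERENCE_LABEL
    }
    return msa, seqs


def reconstruct_founders(
    graph: VariantGraph,
    variants: list[VariantRecordLite],
    haplotype_labels: list[str],
    L: int,
    f: int | None = None,
    fill: str = "dup",
    include_reference: bool = True,
) -> tuple[Segmentation, SegmentPathTable, FounderSet, ReferenceGuidedMSA, dict[str, str]]:
    """Convenience pipeline: segmentation, joining and emission in one call.

    ``f`` defaults to the segmentation bound (the maximum distinct count
    over segments).
    """
    paths = haplotype_paths(graph, variants, haplotype_labels)
    seg = optimal_segmentation(graph, paths, L)
    table = build_segment_tables(paths, seg)
    if f is None:
        f = table.max_distinct
    fset = greedy_join(table, f, fill=fill)
    msa, seqs = emit_founders(fset, graph, table, include_reference)
    return seg, table, fset, msa, seqs
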