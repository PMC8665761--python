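"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the code paths it validates:
haplotypes by direct splicing, aligned positions by exhaustive path
enumeration, bridges by path intersection, segmentation by exhaustive
subset search, LZ factor lengths by a naive scan, and edit distance by
the textbook quadratic DP.
"""

from __future__ import annotations

import itertools
from collections import Counter

from founderpan.msa_graph import VariantGraph, VariantRecordLite


def splice_haplotype(
    reference: str, variants: list[VariantRecordLite], label: str
) -> str:
    """Apply a haplotype's variants to the reference by direct splicing."""
    chosen = [
        (v.pos, v.end, v.alt_alleles[v.genotypes[label] - 1])
        for v in variants
        if v.genotypes.get(label, 0) > 0
    ]
    seq = reference
    for pos, end, alt in sorted(chosen, reverse=True):
        seq = seq[: pos - 1] + alt + seq[end - 1 :]
    return seq


def all_edges(graph: VariantGraph):
    return list(graph.ref_edges.values()) + list(graph.alt_edges)


def enumerate_paths(graph: VariantGraph, start: int | None = None):
    """All source-to-sink edge paths (exponential; tiny graphs only)."""
    start = graph.nodes[0] if start is None else start
    sink = graph.R + 1
    out_edges: dict[int, list] = {}
    for e in all_edges(graph):
        out_edges.setdefault(e.source, []).append(e)

    def walk(node, acc):
        if node == sink:
            yield list(acc)
            return
        for e in out_edges.get(node, []):
            acc.append(e)
            yield from walk(e.target, acc)
            acc.pop()

    yield from walk(start, [])


def exhaustive_aligned_positions(graph: VariantGraph) -> dict[int, int]:
    """aligned_pos(r) = 1 + max label length over all paths from node 1 to r."""
    result = {graph.nodes[0]: 1}
    out_edges: dict[int, list] = {}
    for e in all_edges(graph):
        out_edges.setdefault(e.source, []).append(e)

    def paths_to(node):
        if node == graph.nodes[0]:
            yield 0
            return
        for e in all_edges(graph):
            if e.target == node:
                for ln in paths_to(e.source):
                    yield ln + len(e.label)

    for node in graph.nodes[1:]:
        result[node] = 1 + max(paths_to(node))
    return result


def bridges_by_path_enumeration(graph: VariantGraph) -> list[tuple[int, int]]:
    """Reference edges present in every source-to-sink path."""
    shared = None
    for path in enumerate_paths(graph):
        edges = {(e.source, e.target, e.label, e.kind) for e in path}
        shared = edges if shared is None else shared & edges
    return sorted(
        (s, t) for s, t, _, kind in (shared or set()) if kind == "reference"
    )


def restriction_counts(paths: dict[str, list], a: int, b: int) -> Counter:
    """Distinct subsequence counts over [a, b) by direct label slicing."""
    counts: Counter = Counter()
    for path in paths.values():
        parts = [e.label for e in path if e.source >= a and e.target <= b]
        counts["".join(parts)] += 1
    return counts


def exhaustive_segmentation_optimum(
    graph: VariantGraph, paths: dict[str, list], interior_Q: list[int], L: int
) -> int:
    """Min over all cut subsets (all segments >= L) of max distinct count,
    with the uncut single segment as fallback when nothing is feasible."""
    sink = graph.R + 1
    best = None
    for k in range(len(interior_Q) + 1):
        for cuts in itertools.combinations(interior_Q, k):
            bounds = [1, *cuts, sink]
            if any(b - a < L for a, b in zip(bounds, bounds[1:])):
                continue
            value = max(
                len(restriction_counts(paths, a, b))
                for a, b in zip(bounds, bounds[1:])
            )
            if best is None or value < best:
                best = value
    if best is None:
        best = len(restriction_counts(paths, 1, sink))
    return best


def naive_lpf(text: str, i: int) -> int:
    """Longest prefix of text[i:] with a full occurrence inside text[:i]."""
    best = 0
    for j in range(i):
        ln = 0
        while (
            j + ln < i
            and i + ln < len(text)
            and text[j + ln] == text[i + ln]
        ):
            ln += 1
        best = max(best, ln)
    return best


def quadratic_edit_distance(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def random_nonoverlapping_variants(rng, reference: str, n_variants: int,
                                   samples: list[str], max_ref_len: int = 4,
                                   max_alt_len: int = 6):
    """Random non-overlapping variant records with haploid genotypes."""
    R = len(reference)
    records = []
    occupied = []
    attempts = 0
    while len(records) < n_variants and attempts < 200:
        attempts += 1
        ref_len = int(rng.integers(1, max_ref_len + 1))
        if R - ref_len < 1:
            continue
        pos = int(rng.integers(1, R - ref_len + 2))
        end = pos + ref_len
        if any(pos < e and end > s for s, e in occupied):
            continue
        occupied.append((pos, end))
        n_alts = int(rng.integers(1, 3))
        alts = set()
        while len(alts) < n_alts:
            ln = int(rng.integers(1, max_alt_len + 1))
            alt = "".join("ACGT"[int(k)] for k in rng.integers(0, 4, ln))
            if alt != reference[pos - 1 : end - 1]:
                alts.add(alt)
        alts = tuple(sorted(alts))
        genotypes = {
            s: int(rng.integers(0, len(alts) + 1)) for s in samples
        }
        records.append(
            VariantRecordLite(
                pos=pos,
                ref_allele=reference[pos - 1 : end - 1],
                alt_alleles=alts,
                genotypes=genotypes,
                id=f"v{len(records)}",
            )
        )
    return records


def random_sequence(rng, length: int) -> str:
    return "".join("ACGT"[int(k)] for k in rng.integers(0, 4, length))
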