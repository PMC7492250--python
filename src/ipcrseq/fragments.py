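"""Short-fragment de Bruijn assembly.

The second, parallel assembly route: 500 primer-bearing long reads are split
into non-overlapping 200 bp fragments and assembled through a de Bruijn
graph of canonical k-mers.  Error k-mers are removed by a minimum-count
filter; maximal non-branching paths are compressed into unitigs.  The
unitigs recover sequence close to the screening element that the long-read
draft contigs tend to miss, and are later used to extend them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ReadRecord, reverse_complement
from .draft import Contig


@dataclass
class Fragment:
    """A window of a parent read; fragments shorter than k are discarded."""

    id: str
    seq: str
    parent_offset: int


def sample_reads(
    reads: list[ReadRecord], n: int = 500, rng: np.random.Generator | int = 0
) -> list[ReadRecord]:
    """Sample ``n`` reads without replacement (all reads if the pool is small)."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if len(reads) <= n:
        if len(reads) < n:
            warnings.warn(f"pool of {len(reads)} smaller than requested {n}; using all")
        return list(reads)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in sorted(idx)]


def split_into_fragments(
    reads: list[ReadRecord], fragment_size: int = 200, k: int = 21
) -> list[Fragment]:
    """Cut each read into consecutive non-overlapping ``fragment_size`` windows.

    The trailing window is kept when it is at least ``k`` bp (it still
    contributes k-mers); shorter tails are dropped.
    """
    if fragment_size <= k:
        raise ValueError("fragment_size must exceed k")
    frags: list[Fragment] = []
    for r in reads:
        for ordinal, off in enumerate(range(0, len(r.seq), fragment_size)):
            piece = r.seq[off : off + fragment_size]
            if len(piece) >= k:
                frags.append(Fragment(id=f"{r.id}/{ordinal}", seq=piece, parent_offset=off))
    return frags


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def count_kmers(fragments: list[Fragment], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for f in fragments:
        s = f.seq
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if "N" in km:
                continue
            km = canonical(km)
            counts[km] = counts.get(km, 0) + 1
    return counts


def debruijn_assemble(
    fragments: list[Fragment],
    k: int = 21,
    min_kmer_count: int = 2,
    label: str = "unitig",
) -> list[Contig]:
    """Unitigs of the de Bruijn graph over count-filtered canonical k-mers.

    k must be odd (no self-reverse-complement k-mers).  Nodes are
    (k-1)-mers, edges are surviving k-mers; maximal non-branching paths are
    compressed and reported when at least ``2k`` bp long.  Output is
    independent of fragment order and strand: each unitig is reported once,
    as the lexicographically smaller of itself and its reverse complement.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    counts = count_kmers(fragments, k)
    kmers = {km for km, c in counts.items() if c >= min_kmer_count}
    if not kmers:
        warnings.warn("no k-mers survive the count filter; no unitigs")
        return []
    edges = set(kmers) | {reverse_complement(km) for km in kmers}
    outgoing: dict[str, list[str]] = {}
    incoming: dict[str, list[str]] = {}
    for km in edges:
        u, v = km[:-1], km[1:]
        outgoing.setdefault(u, []).append(km)
        incoming.setdefault(v, []).append(km)

    def outdeg(node: str) -> int:
        return len(outgoing.get(node, ()))

    def indeg(node: str) -> int:
        return len(incoming.get(node, ()))

    unitigs: set[str] = set()
    visited: set[str] = set()
    for km in sorted(edges):
        if km in visited:
            continue
        u = km[:-1]
        if indeg(u) == 1 and outdeg(u) == 1:
            continue  # interior edge; will be reached from a branch point
        # walk forward from a branch/tip start
        path = [km]
        pathset = {km}
        visited.add(km)
        node = km[1:]
        while indeg(node) == 1 and outdeg(node) == 1:
            nxt = outgoing[node][0]
            if nxt in pathset:
                break  # perfect cycle guard
            path.append(nxt)
            pathset.add(nxt)
            visited.add(nxt)
            node = nxt[1:]
        seq = path[0] + "".join(p[-1] for p in path[1:])
        unitigs.add(min(seq, reverse_complement(seq)))
    # isolated simple cycles: every edge interior
    for km in sorted(edges):
        if km in visited:
            continue
        path = [km]
        pathset = {km}
        visited.add(km)
        node = km[1:]
        while True:
            nxt = outgoing[node][0]
            if nxt in pathset:
                break
            path.append(nxt)
            pathset.add(nxt)
            visited.add(nxt)
            node = nxt[1:]
        seq = path[0] + "".join(p[-1] for p in path[1:])
        unitigs.add(min(seq, reverse_complement(seq)))
    out = [
        Contig(id=f"{label}_{i}", seq=s, provenance={"stage": "fragment_assembly", "k": k})
        for i, s in enumerate(sorted(unitigs, key=lambda s: (-len(s), s)))
        if len(s) >= 2 * k
    ]
    return out
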