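"""Read mapping, pileup consensus polishing, depth and identity reporting.

The polishing stage maps every selected read back to the merged sequence
with a seed-and-align strategy, then takes a per-column majority vote
(substitutions, deletions, and insertion consensus when a majority of
spanning reads insert the same sequence at a boundary).  Mapping and voting
iterate to a fixed point (at most 5 rounds).  The same machinery produces
the final report: depth statistics, percent identity against a reference
and the plant/transgene junction coordinate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np

import edlib

from .align import edlib_ops, local_align
from .core import AlignmentRecord, ReadRecord, reverse_complement


@dataclass
class DepthProfile:
    """Per-position coverage and base votes over a consensus sequence."""

    depth: np.ndarray  # total votes per position (bases + deletion votes)
    base_counts: dict  # base -> count vector, bases "ACGTN-"

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class JunctionCall:
    position: int
    plant_interval: tuple[int, int]
    transgene_interval: tuple[int, int]


@dataclass
class ConsensusReport:
    sequence: str
    depth_min: int
    depth_max: int
    depth_mean: float
    identity_vs_reference: float
    shared_span: int
    junction_position: Optional[int]
    flank_len: Optional[int]
    insert_len: Optional[int]

    def as_text(self) -> str:
        lines = [
            f"consensus length\t{len(self.sequence)}",
            f"depth min\t{self.depth_min}",
            f"depth max\t{self.depth_max}",
            f"depth mean\t{round(self.depth_mean)}",
            f"identity vs reference\t{self.identity_vs_reference:.1f}% over {self.shared_span} bp",
        ]
        if self.junction_position is not None:
            lines.append(f"plant/transgene junction\t{self.junction_position}")
            lines.append(f"plant flank\t{self.flank_len} bp")
            lines.append(f"insert (covered)\t{self.insert_len} bp")
        return "\n".join(lines) + "\n"


def _kmer_index(reference: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(reference) - k + 1):
        idx.setdefault(reference[i : i + k], []).append(i)
    return idx


def map_reads(
    reads: list[ReadRecord],
    reference: str,
    k: int = 15,
    band: int = 200,
    min_identity: float = 0.70,
    min_span: int = 200,
    index: dict | None = None,
) -> list[AlignmentRecord]:
    """Map each read to the reference by k-mer seeding plus banded alignment.

    The best-voted strand/diagonal picks a reference window (padded by
    ``band``); the read is then infix-aligned inside the window with edlib.
    Reads failing ``min_identity`` over ``min_span`` aligned bases stay
    unmapped.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    idx = index if index is not None else _kmer_index(reference, k)
    out: list[AlignmentRecord] = []
    for read in reads:
        best = _map_one(read, reference, idx, k, band, min_identity, min_span)
        if best is not None:
            out.append(best)
    return out


def _map_one(read, reference, idx, k, band, min_identity, min_span):
    best = None
    for strand in "+-":
        if best is not None and best.identity >= 0.85:
            break  # unambiguous plus-strand hit; skip the minus strand
        seq = read.seq if strand == "+" else reverse_complement(read.seq)
        diags: Counter = Counter()
        positions: dict[int, list[int]] = {}
        for p in range(0, len(seq) - k + 1, 3):
            for t in idx.get(seq[p : p + k], ()):
                b = (t - p) // 100
                diags[b] += 1
                positions.setdefault(b, []).append(t - p)
        if not diags:
            continue
        bucket, votes = max(diags.items(), key=lambda kv: (kv[1], -kv[0]))
        if votes < 3:
            continue
        ds = positions[bucket] + positions.get(bucket - 1, []) + positions.get(bucket + 1, [])
        lo = max(0, min(ds) - band)
        hi = min(len(reference), max(ds) + len(seq) + band)
        window = reference[lo:hi]
        res = edlib.align(seq, window, mode="HW", k=int((1 - min_identity) * len(seq) * 1.2) + 20)
        if res["editDistance"] < 0:
            continue
        ts, te, ops = edlib_ops(seq, window, mode="HW")
        matches = sum(n for op, n in ops if op == "=")
        cols = sum(n for _, n in ops)
        ident = matches / cols if cols else 0.0
        span = te - ts
        if ident < min_identity or span < min_span:
            continue
        rec = AlignmentRecord(
            query_id=read.id,
            target_id="reference",
            q_interval=(0, len(seq)),
            t_interval=(lo + ts, lo + te),
            strand=strand,
            identity=ident,
            score=float(matches),
            ops=ops,
        )
        if best is None or rec.score > best.score:
            best = rec
    return best


def pileup_consensus(
    alignments: list[AlignmentRecord],
    reads: list[ReadRecord],
    reference: str,
    max_rounds: int = 5,
    map_kwargs: dict | None = None,
    min_end_depth: int = 5,
) -> tuple[str, DepthProfile]:
    """Majority-vote polish of ``reference``, iterated to a fixed point.

    Per column, the majority base among aligned bases wins; deletion votes
    may remove a column; an insertion is applied between columns when more
    than half of the reads spanning that boundary insert the same sequence.
    Ties keep the reference base.  After a change the reads are re-mapped to
    the new consensus (at most ``max_rounds`` rounds).  Finally the
    consensus is trimmed to its outermost positions with at least
    ``min_end_depth`` supporting reads — a majority call is not meaningful
    on single-molecule fringes, which is also where circularization-junction
    chimera accumulate.  Returns the polished sequence and the depth profile
    of the final mapping.
    """
    if not alignments:
        raise ValueError("pileup_consensus requires at least one mapped read")
    by_id = {r.id: r for r in reads}
    mapped_reads = [by_id[a.query_id] for a in alignments]
    consensus = reference
    profile = None
    for round_no in range(max_rounds):
        new_seq, profile = _vote(alignments, by_id, consensus)
        if new_seq == consensus:
            break
        consensus = new_seq
        kwargs = map_kwargs or {}
        alignments = map_reads(mapped_reads, consensus, **kwargs)
        if not alignments:
            raise ValueError("all reads unmapped after polishing round")
    else:
        _, profile = _vote(alignments, by_id, consensus)
    return trim_to_support(consensus, profile, min_end_depth)


def trim_to_support(
    consensus: str, profile: DepthProfile, min_end_depth: int
) -> tuple[str, DepthProfile]:
    """Trim consensus ends to the outermost positions with enough support."""
    if min_end_depth <= 1:
        return consensus, profile
    ok = np.nonzero(profile.depth >= min_end_depth)[0]
    if len(ok) == 0:
        return consensus, profile
    lo, hi = int(ok[0]), int(ok[-1]) + 1
    if lo == 0 and hi == len(consensus):
        return consensus, profile
    trimmed = DepthProfile(
        depth=profile.depth[lo:hi].copy(),
        base_counts={b: v[lo:hi].copy() for b, v in profile.base_counts.items()},
    )
    return consensus[lo:hi], trimmed


_BASES6 = "ACGTN-"
_CODE6 = np.zeros(128, dtype=np.int8)
for _i, _c in enumerate(_BASES6):
    _CODE6[ord(_c)] = _i


def _codes6(s: str) -> np.ndarray:
    return _CODE6[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def _vote(alignments, reads_by_id, reference):
    L = len(reference)
    mat = np.zeros((6, L), dtype=np.int32)  # rows: A C G T N gap-vote
    inserts: dict[int, Counter] = {}
    spanning = np.zeros(L + 1, dtype=np.int32)
    code_chunks: list[np.ndarray] = []
    pos_chunks: list[np.ndarray] = []
    for a in alignments:
        read = reads_by_id[a.query_id]
        seq = read.seq if a.strand == "+" else reverse_complement(read.seq)
        codes = _codes6(seq)
        tpos = a.t_interval[0]
        qpos = 0
        spanning[tpos + 1 : a.t_interval[1]] += 1
        for op, n in a.ops:
            if op in ("=", "X"):
                code_chunks.append(codes[qpos : qpos + n])
                pos_chunks.append(np.arange(tpos, tpos + n))
                tpos += n
                qpos += n
            elif op == "D":  # target-only: read votes a deletion
                mat[5, tpos : tpos + n] += 1
                tpos += n
            else:  # I: query-only bases -> insertion at boundary tpos
                if 0 < tpos < L:
                    inserts.setdefault(tpos, Counter())[seq[qpos : qpos + n]] += 1
                qpos += n
    if code_chunks:
        np.add.at(mat, (np.concatenate(code_chunks), np.concatenate(pos_chunks)), 1)
    ref_codes = _codes6(reference)
    top = mat.max(axis=0)
    winner = mat.argmax(axis=0)  # first max in ACGTN- order
    # ties keep the reference base
    ref_is_top = mat[ref_codes, np.arange(L)] == top
    winner = np.where(ref_is_top, ref_codes, winner)
    winner = np.where(top == 0, ref_codes, winner)  # uncovered: keep reference
    base_arr = np.frombuffer(_BASES6.encode(), dtype=np.uint8)[winner]
    keep = winner != 5
    if not inserts:
        out_seq = base_arr[keep].tobytes().decode("ascii")
    else:
        pieces: list[str] = []
        prev = 0
        for i in sorted(inserts):
            if spanning[i] > 0:
                ins_seq, c = inserts[i].most_common(1)[0]
                if c > 0.5 * spanning[i]:
                    pieces.append(base_arr[prev:i][keep[prev:i]].tobytes().decode("ascii"))
                    pieces.append(ins_seq)
                    prev = i
        pieces.append(base_arr[prev:][keep[prev:]].tobytes().decode("ascii"))
        out_seq = "".join(pieces)
    depth = mat.sum(axis=0)
    counts = {b: mat[i].copy() for i, b in enumerate(_BASES6)}
    profile = DepthProfile(depth=depth, base_counts=counts)
    return out_seq, profile


def depth_stats(profile: DepthProfile) -> tuple[int, int, float]:
    """(min, max, mean) coverage over the profile; mean rounded on report."""
    if len(profile) == 0:
        raise ValueError("empty depth profile")
    d = profile.depth
    return int(d.min()), int(d.max()), float(d.mean())


def percent_identity(sequence: str, reference: str) -> tuple[float, int]:
    """Percent identity of the best local alignment and the shared span (bp).

    Identity is matches over aligned columns, as a percentage; the span is
    the number of aligned reference bases.  Returns (0, 0) when no local
    alignment of at least 100 bp exists.
    """
    if not sequence or not reference:
        raise ValueError("percent_identity requires non-empty sequences")
    best = None
    for strand, seq in (("+", sequence), ("-", reverse_complement(sequence))):
        rec = local_align(seq, reference, query_id="sequence", target_id="reference")
        if best is None or rec.score > best.score:
            best = rec
    span = best.t_interval[1] - best.t_interval[0]
    if span < 100:
        import warnings

        warnings.warn("no shared span of at least 100 bp; reporting (0, 0)")
        return 0.0, 0
    return 100.0 * best.identity, span


def locate_junction(
    consensus: str,
    plant_reference: str,
    transgene_reference: str,
    min_identity: float = 0.90,
    min_span: int = 200,
) -> Optional[JunctionCall]:
    """Locate the plant/transgene junction on the consensus.

    Both references are locally aligned to the consensus; the junction is
    the last consensus position assigned to the plant alignment (0-based:
    the transgene starts at the junction position).  ``None`` when either
    reference fails to align at ``min_identity`` over ``min_span``.
    """
    plant = local_align(plant_reference, consensus, query_id="plant", target_id="consensus")
    tg = local_align(transgene_reference, consensus, query_id="transgene", target_id="consensus")
    for rec in (plant, tg):
        span = rec.t_interval[1] - rec.t_interval[0]
        if rec.identity < min_identity or span < min_span:
            return None
    return JunctionCall(
        position=plant.t_interval[1],
        plant_interval=plant.t_interval,
        transgene_interval=tg.t_interval,
    )


def write_bedgraph(profile: DepthProfile, handle, name: str = "consensus") -> None:
    d = profile.depth
    start = 0
    for i in range(1, len(d) + 1):
        if i == len(d) or d[i] != d[start]:
            handle.write(f"{name}\t{start}\t{i}\t{int(d[start])}\n")
            start = i


def build_report(
    consensus: str,
    profile: DepthProfile,
    reference: str,
    junction: Optional[JunctionCall],
) -> ConsensusReport:
    dmin, dmax, dmean = depth_stats(profile)
    ident, span = percent_identity(consensus, reference)
    if junction is not None:
        flank = junction.position
        insert = len(consensus) - junction.position
    else:
        flank = insert = None
    return ConsensusReport(
        sequence=consensus,
        depth_min=dmin,
        depth_max=dmax,
        depth_mean=dmean,
        identity_vs_reference=ident,
        shared_span=span,
        junction_position=junction.position if junction else None,
        flank_len=flank,
        insert_len=insert,
    )
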