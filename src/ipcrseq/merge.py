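"""Extend oriented draft contigs with fragment-assembly unitigs and join them.

The two oriented draft contigs sit on either side of the known screening
element: one ends in the element's left portion (upstream arm), the other
starts in its right portion (downstream arm).  Unitigs from the short-
fragment assembly are aligned to each contig and, when a unitig overhangs a
contig end, the overhang is appended (draft bases are never altered inside
the overlap — the draft derives from far more data).  The two extended
contigs are then joined either through a direct overlap or through the known
seed sequence itself, yielding one linear sequence in locus orientation.
"""

from __future__ import annotations

import warnings

from .align import edit_distance, local_align
from .core import AlignmentRecord, reverse_complement
from .draft import Contig

_END_SLACK = 25  # bp an alignment may stop short of a contig end and still anchor it
_MAX_ROUNDS = 20


def match_unitigs(
    unitigs: list[Contig],
    draft: Contig,
    min_identity: float = 0.90,
    min_match: int = 100,
) -> list[AlignmentRecord]:
    """Local alignments of each unitig (either strand) to an oriented draft.

    Only matches of at least ``min_match`` aligned bases at
    ``min_identity`` are kept, sorted by draft coordinate.
    """
    if not draft.oriented:
        raise ValueError("draft contig must be oriented before unitig matching")
    out: list[AlignmentRecord] = []
    for u in unitigs:
        best = None
        for strand, seq in (("+", u.seq), ("-", reverse_complement(u.seq))):
            rec = local_align(seq, draft.seq, query_id=u.id, target_id=draft.id)
            rec.strand = strand
            if best is None or rec.score > best.score:
                best = rec
        span = best.t_interval[1] - best.t_interval[0]
        if best.identity >= min_identity and span >= min_match:
            out.append(best)
    out.sort(key=lambda r: (r.t_interval, r.query_id))
    return out


def extend_contig(
    draft: Contig,
    unitigs: list[Contig],
    matches: list[AlignmentRecord] | None = None,
    min_identity: float = 0.90,
    min_match: int = 100,
) -> Contig:
    """Extend both ends of a draft contig with overhanging matched unitigs.

    Per end and per round, the matching unitig with the longest overhang past
    that end is spliced on: draft bases are kept over the overlap, only the
    unitig overhang is appended.  Repeats until no unitig extends further
    (at most 20 rounds).  When two unitigs overhang the same end but
    disagree (< 90% identity over their shared span), the longer match wins
    with a warning.
    """
    by_id = {u.id: u for u in unitigs}
    seq = draft.seq
    extensions: list[str] = []
    for _ in range(_MAX_ROUNDS):
        work = Contig(id=draft.id, seq=seq, oriented=True)
        ms = (
            matches
            if matches is not None and seq == draft.seq
            else match_unitigs(unitigs, work, min_identity, min_match)
        )
        grown = False
        for end in ("left", "right"):
            cands = []
            for rec in ms:
                u = by_id[rec.query_id]
                useq = u.seq if rec.strand == "+" else reverse_complement(u.seq)
                qs, qe = rec.q_interval
                ts, te = rec.t_interval
                if end == "left" and ts <= _END_SLACK and qs - ts > 0:
                    cands.append((qs - ts, rec, useq[: qs - ts]))
                elif end == "right" and len(seq) - te <= _END_SLACK:
                    tail = (len(useq) - qe) - (len(seq) - te)
                    if tail > 0:
                        cands.append((tail, rec, useq[len(useq) - tail :]))
            if not cands:
                continue
            cands.sort(key=lambda c: (-c[0], c[1].query_id))
            if len(cands) > 1:
                _warn_on_conflict(cands, end)
            overhang = cands[0][2]
            if end == "left":
                seq = overhang + seq
            else:
                seq = seq + overhang
            extensions.append(f"{end}:{cands[0][1].query_id}:+{len(overhang)}bp")
            grown = True
        if not grown:
            break
    return Contig(
        id=draft.id,
        seq=seq,
        quals=None,
        provenance={**draft.provenance, "extensions": extensions},
        oriented=draft.oriented,
        seed_interval=None,  # coordinates shifted; re-locate when needed
    )


def _warn_on_conflict(cands, end):
    (l1, r1, o1), (l2, r2, o2) = cands[0], cands[1]
    shared = min(len(o1), len(o2))
    if shared < 20:
        return
    a = o1[-shared:] if end == "left" else o1[:shared]
    b = o2[-shared:] if end == "left" else o2[:shared]
    d = edit_distance(a, b)
    if d > 0.10 * shared:
        warnings.warn(
            f"conflicting {end} extensions {r1.query_id} vs {r2.query_id}; keeping the longer match"
        )


def join_contigs(
    contig_a: Contig,
    contig_b: Contig,
    known_seed: str,
    min_overlap: int = 50,
    min_identity: float = 0.90,
) -> str:
    """Join the two arm contigs into one sequence through the known seed.

    The upstream arm (A) carries the *upstream half* of the seed near its
    end; the downstream arm (B) carries the downstream half at its start.
    Classification therefore aligns the two seed halves separately and
    picks the assignment with the higher combined score — a full-seed hit
    is ambiguous because a contig's chimeric fringe can contain the other
    arm's seed half.  Terminal segments of one contig that duplicate the
    other contig's seed-adjacent region (junction-read debris) are trimmed
    before joining.  If A's tail and B's head overlap directly
    (>= ``min_overlap`` bp at >= 90% identity) they are merged through the
    overlap with A's bases kept; otherwise the join runs through the seed
    itself: A up to its upstream-half hit, the full seed, then B after its
    downstream-half hit.  Raises when the seed is found in neither contig.
    """
    for c in (contig_a, contig_b):
        if not c.oriented:
            raise ValueError("contigs must be oriented before joining")
    found = []
    for c in (contig_a, contig_b):
        rec = local_align(known_seed, c.seq, query_id="seed", target_id=c.id)
        span = rec.q_interval[1] - rec.q_interval[0]
        found.append(rec.identity >= 0.80 and span >= 30)
    if not any(found):
        raise ValueError("known seed found in neither contig; cannot join")
    if found.count(True) == 1:
        only = contig_a if found[0] else contig_b
        warnings.warn("seed found in only one contig; returning it unjoined")
        return only.seq
    mid = len(known_seed) // 2
    prefix, suffix = known_seed[:mid], known_seed[mid:]

    def half_hits(c: Contig):
        hp = local_align(prefix, c.seq, query_id="seed5", target_id=c.id)
        hs = local_align(suffix, c.seq, query_id="seed3", target_id=c.id)
        return hp, hs

    hp_a, hs_a = half_hits(contig_a)
    hp_b, hs_b = half_hits(contig_b)
    if hp_a.score + hs_b.score >= hp_b.score + hs_a.score:
        A, B = contig_a, contig_b
    else:
        A, B = contig_b, contig_a
    A_seq = _trim_cross_duplication(A.seq, B.seq)
    B_seq = _trim_cross_duplication(B.seq[::-1], A.seq[::-1])[::-1]
    rec_a = local_align(prefix, A_seq, query_id="seed5", target_id=A.id)
    rec_b = local_align(suffix, B_seq, query_id="seed3", target_id=B.id)
    # direct-overlap attempt between A's tail and B's head
    tail_len = min(len(A_seq), len(A_seq) - rec_a.t_interval[0] + 500)
    head_len = min(len(B_seq), rec_b.t_interval[1] + 500)
    tail = A_seq[len(A_seq) - tail_len :]
    head = B_seq[:head_len]
    if tail and head:
        ov = local_align(tail, head, query_id="A_tail", target_id="B_head")
        span = ov.t_interval[1] - ov.t_interval[0]
        reaches_a_end = (tail_len - ov.q_interval[1]) <= _END_SLACK
        reaches_b_start = ov.t_interval[0] <= _END_SLACK
        if span >= min_overlap and ov.identity >= min_identity and reaches_a_end and reaches_b_start:
            return A_seq + B_seq[ov.t_interval[1] :]
    # join through the seed: A up to its upstream-half hit, the seed, then B
    a_cut = rec_a.t_interval[0] if rec_a.score > 0 else len(A_seq)
    b_cut = rec_b.t_interval[1] if rec_b.score > 0 else 0
    return A_seq[:a_cut] + known_seed + B_seq[b_cut:]


def _trim_cross_duplication(a_seq: str, b_seq: str, window: int = 3000) -> str:
    """Drop a head of ``a_seq`` that duplicates the start of ``b_seq``.

    Reads spanning a circularization junction can deposit a copy of the
    other arm's seed-adjacent sequence at a contig's outer fringe.  Such
    debris is recognizable as a long, high-identity match between one
    contig's head and the other contig's head — genuine arm sequence never
    matches the other arm.  (Applied to reversed sequences, this trims tail
    debris symmetrically.)
    """
    head_a = a_seq[: min(window, max(0, len(a_seq) - 2000))]
    head_b = b_seq[:2000]
    if len(head_a) < 150 or len(head_b) < 150:
        return a_seq
    rec = local_align(head_b, head_a, query_id="other_head", target_id="head")
    span = rec.t_interval[1] - rec.t_interval[0]
    if span >= 150 and rec.identity >= 0.85:
        warnings.warn(
            f"trimmed {rec.t_interval[1]} bp of cross-arm duplicated sequence from a contig end"
        )
        return a_seq[rec.t_interval[1] :]
    return a_seq


def rotate_to_locus(merged: str, known_seed: str) -> tuple[str, tuple[int, int]]:
    """Normalize the merged sequence so the seed lies on its plus strand.

    The amplicon is linear (its ends are the primer sites), so no rotation
    is performed — only an optional reverse complement.  Returns the
    normalized sequence and the seed's coordinates on it.
    """
    fwd = local_align(known_seed, merged, query_id="seed", target_id="merged")
    rc = reverse_complement(merged)
    rev = local_align(known_seed, rc, query_id="seed", target_id="merged")
    if rev.score > fwd.score:
        return rc, rev.t_interval
    return merged, fwd.t_interval
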