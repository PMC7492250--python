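"""Greedy overlap-layout-consensus draft assembly of long reads.

This is the draft-assembly stage of the pipeline: repeated random 300-read
subsamples are each assembled with a greedy OLC, the two longest distinct
contigs across all iterations are kept, and each is oriented by locating the
known screening-element sequence.

Overlaps are found by shared-k-mer seeding on both strands and verified with
a banded edit-distance alignment.  The greedy layout merges the
highest-scoring dovetail overlaps first; a join is vetoed when the layout it
implies disagrees with two or more overlap records against already-placed
reads — this is what keeps molecule-specific circularization junctions
(chimeric with respect to the locus) from fusing the two amplicon arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .align import best_local_align, edit_distance, edlib_ops, local_align
from .core import ReadRecord, reverse_complement

# layout agreement tolerance (bp) when comparing an overlap record against
# the placement implied by a candidate contig join
_OFFSET_TOL = 150
# implied stacking (bp) above which a missing overlap record between two
# cross-group reads counts as layout disagreement; well above min_overlap so
# genuinely detectable overlaps are essentially never missing by chance
_MISSING_OVERLAP_MIN = 600


@dataclass
class Contig:
    id: str
    seq: str
    quals: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)
    oriented: bool = False
    seed_interval: Optional[tuple[int, int]] = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class OverlapRecord:
    """A verified overlap between read ``a`` (forward) and read ``b``.

    ``strand`` is the orientation of ``b`` relative to ``a``; ``offset`` is
    the start of the (oriented) ``b`` sequence in ``a``'s forward frame,
    which may be negative.  Intervals are in ``a``-forward and oriented-``b``
    coordinates respectively.
    """

    a: int
    b: int
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    strand: str
    identity: float
    overlap_len: int
    offset: int

    @property
    def score(self) -> float:
        return self.overlap_len * self.identity


def find_overlaps(
    reads: list[ReadRecord],
    k: int = 15,
    min_overlap: int = 300,
    min_identity: float = 0.80,
    index_step: int = 2,
    query_step: int = 4,
    min_votes: int = 3,
) -> list[OverlapRecord]:
    """All-vs-all overlap candidates by shared k-mers, verified by alignment.

    Dovetail and containment overlaps are both reported.  Identity is
    estimated as ``1 - edit_distance / overlap_len`` over the implied
    overlap region.
    """
    index: dict[str, list[tuple[int, int]]] = {}
    for j, r in enumerate(reads):
        s = r.seq
        for p in range(0, len(s) - k + 1, index_step):
            index.setdefault(s[p : p + k], []).append((j, p))
    lengths = [len(r) for r in reads]
    rc_cache = [reverse_complement(r.seq) for r in reads]
    out: list[OverlapRecord] = []
    for i, r in enumerate(reads):
        li = lengths[i]
        votes: dict[tuple[int, str], list[int]] = {}
        for strand in "+-":
            q = r.seq if strand == "+" else rc_cache[i]
            for p in range(0, len(q) - k + 1, query_step):
                hits = index.get(q[p : p + k])
                if not hits:
                    continue
                pi = p if strand == "+" else li - (p + k)
                for j, pj in hits:
                    if j <= i:
                        continue
                    if strand == "+":
                        votes.setdefault((j, "+"), []).append(pi - pj)
                    else:
                        pj_or = lengths[j] - (pj + k)
                        votes.setdefault((j, "-"), []).append(pi - pj_or)
        for (j, strand), diags in sorted(votes.items()):
            if len(diags) < min_votes:
                continue
            rec = _verify_overlap(i, j, strand, diags, reads, rc_cache, min_overlap, min_identity)
            if rec is not None:
                out.append(rec)
    return out


def _verify_overlap(i, j, strand, diags, reads, rc_cache, min_overlap, min_identity):
    lj = len(reads[j])
    diags.sort()
    off = int(diags[len(diags) // 2])
    li = len(reads[i])
    sj = reads[j].seq if strand == "+" else rc_cache[j]
    if off >= 0:
        ov = min(li - off, lj)
        a_iv, b_iv = (off, off + ov), (0, ov)
    else:
        ov = min(li, lj + off)
        a_iv, b_iv = (0, ov), (-off, -off + ov)
    if ov < min_overlap:
        return None
    sa = reads[i].seq[a_iv[0] : a_iv[1]]
    sb = sj[b_iv[0] : b_iv[1]]
    k_lim = int((1 - min_identity) * ov * 1.2) + 10
    d = edit_distance(sa, sb, mode="NW", k=k_lim)
    if d < 0:
        return None
    ident = 1.0 - d / ov
    if ident < min_identity:
        return None
    return OverlapRecord(i, j, a_iv, b_iv, strand, ident, ov, off)


# ---------------------------------------------------------------------------
# greedy layout


class _Layout:
    """Read placements grouped into proto-contigs.

    Each read has a placement ``(group, start, orient)``: the oriented read
    occupies ``[start, start + len)`` in its group's frame; ``orient`` is +1
    when the read's forward strand matches the group frame.
    """

    def __init__(self, reads: list[ReadRecord]):
        self.reads = reads
        self.lengths = [len(r) for r in reads]
        self.group_of = list(range(len(reads)))
        self.place = [(0, 1) for _ in reads]  # (start, orient) in group frame
        self.members: dict[int, list[int]] = {i: [i] for i in range(len(reads))}

    def placed_interval(self, r: int) -> tuple[int, int, int]:
        s, o = self.place[r]
        return s, s + self.lengths[r], o

    def implied_b_placement(self, rec: OverlapRecord):
        """Placement of rec.b in rec.a's group frame implied by the record."""
        sa, oa = self.place[rec.a]
        la = self.lengths[rec.a]
        lb = self.lengths[rec.b]
        sign = 1 if rec.strand == "+" else -1
        if oa == 1:
            return sa + rec.offset, sign
        return sa + la - rec.offset - lb, -sign

    def predicted_offset(self, x: int, y: int):
        """(offset, strand) of oriented-y in x's forward frame, from placements."""
        sx, ox = self.place[x]
        sy, oy = self.place[y]
        lx, ly = self.lengths[x], self.lengths[y]
        if ox == 1:
            return sy - sx, "+" if oy == 1 else "-"
        return sx + lx - sy - ly, "+" if oy == -1 else "-"

    def merge(self, rec: OverlapRecord) -> None:
        """Merge rec.b's group into rec.a's group using the record geometry."""
        ga, gb = self.group_of[rec.a], self.group_of[rec.b]
        S, O = self.implied_b_placement(rec)
        sb, ob = self.place[rec.b]
        lb = self.lengths[rec.b]
        if O == ob:  # orientation-preserving shift
            delta = S - sb
            for m in self.members[gb]:
                s, o = self.place[m]
                self.place[m] = (s + delta, o)
        else:  # reflect the group frame (s' = C - (s + len)), flipping orients
            C = S + sb + lb
            for m in self.members[gb]:
                s, o = self.place[m]
                self.place[m] = (C - (s + self.lengths[m]), -o)
        for m in self.members[gb]:
            self.group_of[m] = ga
        self.members[ga].extend(self.members[gb])
        del self.members[gb]


def greedy_assemble(
    reads: list[ReadRecord],
    overlaps: list[OverlapRecord],
    min_report_len: int = 1000,
    label: str = "draft",
) -> list[Contig]:
    """Greedy OLC: merge best-scoring overlaps first, veto chimeric joins.

    A candidate join is rejected when, after the hypothetical merge, two or
    more overlap records between reads of the two groups disagree with the
    implied layout (offset off by more than 150 bp or strand flipped).
    Contigs with at least 2 reads or at least ``min_report_len`` bp are
    reported.
    """
    layout = _Layout(reads)
    adj: dict[int, list[OverlapRecord]] = {}
    for rec in overlaps:
        adj.setdefault(rec.a, []).append(rec)
        adj.setdefault(rec.b, []).append(rec)
    pairset = {(min(r.a, r.b), max(r.a, r.b)) for r in overlaps}
    memo: set = set()
    order = sorted(
        overlaps, key=lambda r: (-r.score, reads[r.a].id, reads[r.b].id)
    )
    for rec in order:
        ga, gb = layout.group_of[rec.a], layout.group_of[rec.b]
        if ga == gb:
            continue
        if _vetoed(layout, rec, adj, pairset, memo):
            continue
        layout.merge(rec)
    _reassignment_sweep(layout, adj)
    contigs: list[Contig] = []
    for gid, members in sorted(layout.members.items()):
        contig = _consensus_from_group(layout, members, adj, label, gid)
        if contig is None:
            continue
        n_reads = contig.provenance.get("n_reads", 1)
        if n_reads >= 2 or len(contig) >= min_report_len:
            contigs.append(contig)
    contigs.sort(key=lambda c: (-len(c), c.id))
    return contigs


def _vetoed(layout: _Layout, rec: OverlapRecord, adj, pairset=None, memo=None) -> bool:
    """Would rec's join contradict at least two already-placed reads?

    Two kinds of contradiction count: an existing overlap record between the
    two groups whose offset or strand disagrees with the implied layout, and
    a *missing* overlap — a cross-group read pair that the implied layout
    stacks on top of each other by a wide margin yet for which no overlap was
    ever verified (the signature of a molecule-specific shear junction).
    """
    ga, gb = layout.group_of[rec.a], layout.group_of[rec.b]
    # hypothetically place rec.b's group into rec.a's frame to compare offsets
    S, O = layout.implied_b_placement(rec)
    sb, ob = layout.place[rec.b]
    # groups only grow, so a vetoed (group, group, placement) can only
    # accumulate more disagreement: positive veto results are cacheable
    key = (ga, gb, O, S // 300)
    if memo is not None and key in memo:
        return True
    disagreements = 0
    scanned = 0
    small = ga if len(layout.members[ga]) <= len(layout.members[gb]) else gb
    for y in layout.members[small]:
        if scanned >= 60:
            break  # decision from the first 60 cross-records is stable
        for r2 in adj.get(y, ()):
            if r2 is rec:
                continue
            x = r2.b if r2.a == y else r2.a
            gx = layout.group_of[x]
            if {gx, layout.group_of[y]} != {ga, gb}:
                continue
            scanned += 1
            pred = _cross_offset(layout, r2, rec, S, O)
            if pred is None:
                continue
            off_pred, strand_pred = pred
            # k-mer median offsets drift with overlap length; scale the
            # agreement window so long overlaps are not spuriously flagged
            tol = max(_OFFSET_TOL, int(0.08 * r2.overlap_len))
            if strand_pred != r2.strand or abs(off_pred - r2.offset) > tol:
                disagreements += 1
                if disagreements >= 2:
                    if memo is not None:
                        memo.add(key)
                    return True
    if pairset is None:
        return False
    # negative evidence: deeply stacked cross-group pairs with no record.
    # restrict to reads near the join region; that is where contradictions
    # of a chimeric join concentrate
    lb = layout.lengths[rec.b]
    w_lo, w_hi = S - 4000, S + lb + 4000
    placed_b = _hypothetical_placements(layout, rec, S, O)
    gb_members = [
        (m, placed_b[m])
        for m in layout.members[gb]
        if w_lo <= placed_b[m][0] <= w_hi
    ][:80]
    ga_members = [
        (m, layout.place[m])
        for m in layout.members[ga]
        if w_lo <= layout.place[m][0] <= w_hi
    ][:80]
    for y, (sy, _oy) in gb_members:
        ey = sy + layout.lengths[y]
        for x, (sx, _ox) in ga_members:
            ex = sx + layout.lengths[x]
            implied = min(ey, ex) - max(sy, sx)
            if implied < _MISSING_OVERLAP_MIN:
                continue
            pair = (x, y) if x < y else (y, x)
            if pair not in pairset:
                disagreements += 1
                if disagreements >= 2:
                    if memo is not None:
                        memo.add(key)
                    return True
    return False


def _hypothetical_placements(layout: _Layout, rec: OverlapRecord, S: int, O: int):
    """Placements of rec.b's group members in rec.a's frame if rec merged."""
    gb = layout.group_of[rec.b]
    sb, ob = layout.place[rec.b]
    lb = layout.lengths[rec.b]
    out = {}
    for m in layout.members[gb]:
        s, o = layout.place[m]
        if O == ob:
            out[m] = (s + (S - sb), o)
        else:
            C = S + sb + lb
            out[m] = (C - (s + layout.lengths[m]), -o)
    return out


def _cross_offset(layout: _Layout, r2: OverlapRecord, rec: OverlapRecord, S: int, O: int):
    """Predicted (offset, strand) for record r2 if rec's merge were applied."""
    gb = layout.group_of[rec.b]

    def placed(r: int):
        s, o = layout.place[r]
        if layout.group_of[r] != gb:
            return s, o
        # transform gb frame into ga frame per the hypothetical merge
        sb, ob = layout.place[rec.b]
        lb = layout.lengths[rec.b]
        if O == ob:
            return s + (S - sb), o
        C = S + sb + lb
        return C - (s + layout.lengths[r]), -o

    sx, ox = placed(r2.a)
    sy, oy = placed(r2.b)
    lx, ly = layout.lengths[r2.a], layout.lengths[r2.b]
    if ox == 1:
        return sy - sx, "+" if oy == 1 else "-"
    return sx + lx - sy - ly, "+" if oy == -1 else "-"


def _reassignment_sweep(layout: _Layout, adj, passes: int = 2) -> None:
    """Peel off reads whose overlap evidence points at a different group.

    A single read spanning a circularization junction can bridge genuine
    reads from the other amplicon arm into a group, where they build a
    locally consistent but globally wrong appendage.  Such reads are
    recognizable: most of their overlap records connect them to reads placed
    in another group.  Any read with more cross-group records than
    placement-consistent records in its own group is demoted to a singleton
    (its sequence is already represented in the group it really belongs to).
    """
    next_gid = len(layout.reads)
    for _ in range(passes):
        moved = False
        for r in range(len(layout.reads)):
            own = layout.group_of[r]
            if len(layout.members[own]) <= 1:
                continue
            agree = 0
            votes: dict[int, int] = {}
            for rec in adj.get(r, ()):
                other = rec.b if rec.a == r else rec.a
                g = layout.group_of[other]
                if g == own:
                    off_pred, strand_pred = layout.predicted_offset(rec.a, rec.b)
                    if strand_pred == rec.strand and abs(off_pred - rec.offset) <= _OFFSET_TOL:
                        agree += 1
                else:
                    votes[g] = votes.get(g, 0) + 1
            best_other = max(votes.values()) if votes else 0
            if best_other >= 2 and best_other > agree:
                layout.members[own].remove(r)
                layout.group_of[r] = next_gid
                layout.members[next_gid] = [r]
                layout.place[r] = (0, 1)
                next_gid += 1
                moved = True
        if not moved:
            break


def _consensus_from_group(layout, members, adj, label, gid) -> Optional[Contig]:
    reads = layout.reads
    if len(members) == 1:
        r = reads[members[0]]
        return Contig(
            id=f"{label}_g{gid}",
            seq=r.seq,
            quals=r.quals.copy(),
            provenance={"stage": label, "n_reads": 1, "reads": [r.id]},
        )
    placed = sorted(members, key=lambda m: (layout.place[m][0], reads[m].id))
    base = min(layout.place[m][0] for m in members)

    def oriented(m):
        s, o = layout.place[m]
        if o == 1:
            return reads[m].seq, reads[m].quals
        return reverse_complement(reads[m].seq), reads[m].quals[::-1]

    first = placed[0]
    seq, quals = oriented(first)
    cons = list(seq)
    cq = list(quals)
    cons_end = layout.place[first][0] - base + len(seq)
    used = {first}
    unused = [m for m in placed[1:]]
    n_used = 1
    while True:
        # best extender: overlaps a used read (record-verified), extends furthest
        best_m, best_end = None, cons_end + 20
        for m in unused:
            s = layout.place[m][0] - base
            e = s + len(reads[m])
            if e <= best_end or s > cons_end - 50:
                continue
            if any(
                (r2.a == m and r2.b in used) or (r2.b == m and r2.a in used)
                for r2 in adj.get(m, ())
            ):
                best_m, best_end = m, e
        if best_m is None:
            break
        s = layout.place[best_m][0] - base
        rseq, rquals = oriented(best_m)
        cons, cq, cons_end = _merge_read(cons, cq, cons_end, rseq, rquals, s)
        used.add(best_m)
        unused.remove(best_m)
        n_used += 1
    backbone = "".join(cons)
    refined = _pileup_refine(backbone, [reads[m] for m in members])
    return Contig(
        id=f"{label}_g{gid}",
        seq=refined,
        quals=None,
        provenance={
            "stage": label,
            "n_reads": len(members),
            "n_chained": n_used,
            "reads": [reads[m].id for m in placed],
        },
    )


def _pileup_refine(backbone: str, group_reads, rounds: int = 2) -> str:
    """Majority-vote the group's reads over the chained backbone.

    The join-time consensus only ever votes two sequences at a time, leaving
    contigs near read-level accuracy; realigning every layout member and
    taking a per-column majority brings the draft to consensus-grade
    accuracy, as a long-read assembler's final consensus stage does.
    """
    from . import polish as polish_mod

    by_id = {r.id: r for r in group_reads}
    cons = backbone
    profile = None
    # 0.80 mapping identity rejects whole reads that straddle a shear
    # junction (their forced full-length alignment runs near 0.75) while
    # true reads at ~6% error sit comfortably above it
    for _ in range(rounds):
        aligns = polish_mod.map_reads(group_reads, cons, min_identity=0.80, min_span=150)
        if not aligns:
            return cons
        new, profile = polish_mod._vote(aligns, by_id, cons)
        if new == cons:
            break
        cons = new
        profile = None
    if profile is None:  # rounds exhausted with a change: re-profile final cons
        aligns = polish_mod.map_reads(group_reads, cons, min_identity=0.80, min_span=150)
        if not aligns:
            return cons
        _, profile = polish_mod._vote(aligns, by_id, cons)
    cons, _ = polish_mod.trim_to_support(cons, profile, min_end_depth=3)
    return cons


def _merge_read(cons, cq, cons_end, rseq, rquals, s):
    """Splice a dovetail read ending past ``cons_end`` onto the consensus.

    The read's layout start ``s`` is refined by anchoring its prefix in a
    window of the consensus, the overlap is aligned column by column, and at
    each disagreeing column the higher-quality variant wins (ties keep the
    consensus, which derives from the longer accumulated sequence).
    """
    anchor_len = min(200, len(rseq))
    w_lo = max(0, s - 150)
    w_hi = min(len(cons), s + anchor_len + 150)
    window = "".join(cons[w_lo:w_hi])
    anchor = rseq[:anchor_len]
    import edlib as _edlib

    res = _edlib.align(anchor, window, mode="HW", k=int(0.45 * anchor_len), task="locations")
    if res["editDistance"] >= 0 and res["locations"] and res["locations"][0][0] is not None:
        s = w_lo + res["locations"][0][0]
    ov_c = cons[s:]
    ov_cq = cq[s:]
    if not ov_c:
        return cons + list(rseq), cq + list(rquals), s + len(rseq)
    ts, te, ops = edlib_ops("".join(ov_c), rseq, mode="SHW")
    merged_s: list[str] = []
    merged_q: list[int] = []
    ci = ri = 0
    last_rq = int(np.mean(rquals)) if len(rquals) else 10
    last_cq = ov_cq[0]
    for op, n in ops:
        for _ in range(n):
            if op in ("=", "X"):
                qc, qr = ov_cq[ci], rquals[ri]
                if op == "=" or qc >= qr:
                    merged_s.append(ov_c[ci])
                    merged_q.append(max(qc, qr) if op == "=" else qc)
                else:
                    merged_s.append(rseq[ri])
                    merged_q.append(qr)
                last_cq, last_rq = qc, qr
                ci += 1
                ri += 1
            elif op == "I":  # consensus-only base; read voted a deletion
                qc = ov_cq[ci]
                if qc >= last_rq:
                    merged_s.append(ov_c[ci])
                    merged_q.append(qc)
                last_cq = qc
                ci += 1
            else:  # read-only base (op D in cons-as-query frame)
                qr = rquals[ri]
                if qr > last_cq:
                    merged_s.append(rseq[ri])
                    merged_q.append(qr)
                last_rq = qr
                ri += 1
    tail_s = list(rseq[ri:])
    tail_q = list(rquals[ri:])
    new_cons = cons[:s] + merged_s + tail_s
    new_q = cq[:s] + merged_q + tail_q
    return new_cons, new_q, len(new_cons)


# ---------------------------------------------------------------------------
# iteration, contig selection, orientation


def iterate_draft(
    reads: list[ReadRecord],
    n: int = 300,
    iterations: int = 10,
    rng: np.random.Generator | int = 0,
    k: int = 15,
    min_overlap: int = 300,
    min_identity: float = 0.80,
) -> list[list[Contig]]:
    """Repeatedly subsample ``n`` reads and assemble each subsample."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    collections: list[list[Contig]] = []
    for it in range(iterations):
        if n <= len(reads):
            idx = rng.choice(len(reads), size=n, replace=False)
            sample = [reads[i] for i in sorted(idx)]
        else:
            warnings.warn(
                f"requested subsample of {n} exceeds pool of {len(reads)}; using all reads"
            )
            sample = list(reads)
        ovls = find_overlaps(sample, k=k, min_overlap=min_overlap, min_identity=min_identity)
        contigs = greedy_assemble(sample, ovls, label=f"iter{it}")
        for c in contigs:
            c.provenance["iteration"] = it
        collections.append(contigs)
    return collections


def contigs_same(
    x: Contig,
    y: Contig,
    dup_identity: float = 0.95,
    dup_coverage: float = 0.90,
) -> bool:
    """Are two contigs the same sequence (either strand)?

    True when one aligns to the other at >= ``dup_identity`` identity over
    >= ``dup_coverage`` of the shorter contig.
    """
    short, long_ = (x, y) if len(x) <= len(y) else (y, x)
    best = best_local_align(short.seq, long_.seq)
    span = best.q_interval[1] - best.q_interval[0]
    return best.identity >= dup_identity and span >= dup_coverage * len(short)


def pick_two_longest_distinct(
    collections: list[list[Contig]],
    dup_identity: float = 0.95,
    dup_coverage: float = 0.90,
) -> list[Contig]:
    """The two longest mutually distinct contigs across all iterations.

    Single-read "contigs" (reported only so that degenerate runs still emit
    something) are considered last: an unpolished raw read — possibly
    spanning a circularization junction — must not displace an assembled,
    consensus-grade contig.
    """
    pool = sorted(
        (c for coll in collections for c in coll),
        key=lambda c: (c.provenance.get("n_reads", 1) < 2, -len(c), c.id),
    )
    if not pool:
        raise ValueError("no contigs produced by any iteration")
    first = pool[0]
    for cand in pool[1:]:
        if not contigs_same(first, cand, dup_identity, dup_coverage):
            return [first, cand]
    warnings.warn("all contigs are versions of one sequence; returning a single contig")
    return [first]


def orient_contig(contig: Contig, known_seed: str) -> Contig:
    """Flip the contig, if needed, so the known seed lies on its plus strand.

    Each arm contig contains only one side of the seed (the seed's middle is
    the unamplified inter-primer gap), so the seed hit is judged by local
    alignment quality: a hit below 80% identity or shorter than 50 bp of the
    seed raises ``ValueError`` (the contig cannot be oriented).
    """
    if len(known_seed) < 50:
        raise ValueError("known seed must be at least 50 bp")
    fwd = local_align(known_seed, contig.seq, query_id="seed", target_id=contig.id)
    rc = reverse_complement(contig.seq)
    rev = local_align(known_seed, rc, query_id="seed", target_id=contig.id)
    rec, seq, flipped = (fwd, contig.seq, False) if fwd.score >= rev.score else (rev, rc, True)
    span = rec.q_interval[1] - rec.q_interval[0]
    if rec.identity < 0.80 or span < 50:
        raise ValueError(f"seed not found in contig {contig.id}")
    quals = contig.quals
    if flipped and quals is not None:
        quals = quals[::-1].copy()
    return Contig(
        id=contig.id,
        seq=seq,
        quals=quals,
        provenance={**contig.provenance, "flipped": flipped},
        oriented=True,
        seed_interval=rec.t_interval,
    )
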