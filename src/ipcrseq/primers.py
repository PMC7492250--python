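"""Primer-bearing read selection.

Replaces the BLAST step of the original workflow: reads longer than 1,000 bp
that contain one of the two inverse-PCR primers (either strand) are kept for
assembly.  Containment is judged by Smith–Waterman local alignment with a
minimum number of matched bases, which tolerates the ~6% read error rate
while keeping random hits in multi-kb reads rare.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .align import DEFAULT_SCORING, local_align
from .core import AlignmentRecord, ReadRecord, reverse_complement
from .simulate import P35S_FORWARD, P35S_REVERSE


@dataclass
class PrimerPair:
    """An outward-facing inverse-PCR primer pair (default: the p35S pair)."""

    forward: str = P35S_FORWARD
    reverse: str = P35S_REVERSE
    label: str = "p35S"

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p or len(p) > 50 or p != p.upper():
                raise ValueError(f"{name} primer must be non-empty uppercase and <= 50 bp")

    def variants(self) -> list[tuple[str, str, str]]:
        """All (name, strand, sequence) search variants."""
        return [
            ("forward", "+", self.forward),
            ("forward", "-", reverse_complement(self.forward)),
            ("reverse", "+", self.reverse),
            ("reverse", "-", reverse_complement(self.reverse)),
        ]


@dataclass
class PrimerHit:
    primer: str
    strand: str
    alignment: AlignmentRecord
    matches: int


def primer_hit(
    read: ReadRecord,
    primers: PrimerPair,
    min_matches: int = 18,
    scoring=DEFAULT_SCORING,
) -> tuple[bool, PrimerHit | None]:
    """Does the read contain one of the primers on either strand?

    True iff the best local alignment of any primer variant against the read
    has at least ``min_matches`` matched bases *of the primer's length*:
    indels inside the primer are tolerated, but the non-matching columns
    (mismatches plus gaps) must fit in the same budget, otherwise long gappy
    alignments in random multi-kb sequence reach the match count by chance.
    """
    best: PrimerHit | None = None
    for name, strand, seq in primers.variants():
        # exact containment short-circuits the DP (common on accurate reads)
        pos = read.seq.find(seq)
        if pos >= 0:
            rec = AlignmentRecord(
                query_id=name,
                target_id=read.id,
                q_interval=(0, len(seq)),
                t_interval=(pos, pos + len(seq)),
                strand="+",
                identity=1.0,
                score=2.0 * len(seq),
                ops=[("=", len(seq))],
            )
            return True, PrimerHit(primer=name, strand=strand, alignment=rec, matches=len(seq))
        rec = local_align(seq, read.seq, scoring, query_id=name, target_id=read.id)
        m = rec.matches
        if rec.columns - m > len(seq) - min_matches:
            m = 0  # too many error columns: not a primer-shaped alignment
        if best is None or m > best.matches or (m == best.matches and rec.score > best.alignment.score):
            best = PrimerHit(primer=name, strand=strand, alignment=rec, matches=m)
    return (best is not None and best.matches >= min_matches), best


def select_reads(
    reads: list[ReadRecord],
    primers: PrimerPair | None = None,
    min_len: int = 1000,
    min_matches: int = 18,
) -> list[ReadRecord]:
    """Reads strictly longer than ``min_len`` that contain a primer.

    Order and duplicates are preserved; an empty result is a warning (the
    pipeline cannot proceed without primer-bearing reads) rather than an
    error.
    """
    primers = primers or PrimerPair()
    selected = [
        r
        for r in reads
        if len(r) > min_len and primer_hit(r, primers, min_matches=min_matches)[0]
    ]
    if not selected:
        warnings.warn("no reads passed primer selection")
    return selected


def hit_table(reads: list[ReadRecord], primers: PrimerPair, min_matches: int = 18):
    """TSV-ready rows (read id, primer, strand, matches, read start, read end)."""
    rows = []
    for r in reads:
        ok, best = primer_hit(r, primers, min_matches=min_matches)
        if ok and best is not None:
            s, e = best.alignment.t_interval
            rows.append((r.id, best.primer, best.strand, best.matches, s, e))
    return rows
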