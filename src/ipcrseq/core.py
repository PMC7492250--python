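"""Sequence records, FASTA/FASTQ I/O, Phred arithmetic and reverse complement.

Conventions used throughout the package:

* all coordinates are 0-based, half-open, on the plus strand of the named
  sequence; strand is recorded separately;
* quality encoding is Sanger Phred+33 only;
* sequences are uppercase strings over the alphabet ``{A, C, G, T, N}``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
PHRED_MIN = 0
PHRED_MAX = 93
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastqParseError(ValueError):
    """Malformed FASTQ input; carries the 1-based line number of the problem."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def clean_seq(seq: str, invalid: str = "error") -> str:
    """Uppercase ``seq`` and enforce the DNA alphabet.

    ``invalid`` selects what happens to characters outside ``{A,C,G,T,N}``:
    ``"error"`` raises ``ValueError``, ``"N"`` maps them to N.
    """
    s = seq.upper()
    if set(s) <= DNA_ALPHABET:
        return s
    if invalid == "N":
        return "".join(c if c in DNA_ALPHABET else "N" for c in s)
    bad = sorted(set(s) - DNA_ALPHABET)
    raise ValueError(f"invalid DNA characters: {bad!r}")


def reverse_complement(s: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (N maps to N)."""
    if not set(s) <= DNA_ALPHABET:
        s = clean_seq(s)  # raises on anything outside the alphabet
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class DnaSequence:
    """A named DNA sequence (primer, contig, reference...)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred qualities.

    ``truth`` optionally carries simulation ground truth as
    ``(amplicon_id, (start, end), strand)`` — the half-open interval of the
    source amplicon the read was drawn from, and the strand it was read on.
    """

    id: str
    seq: str
    quals: np.ndarray
    truth: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quals)} != "
                f"sequence length {len(self.seq)}"
            )
        if len(self.quals) and (self.quals.min() < PHRED_MIN or self.quals.max() > PHRED_MAX):
            raise ValueError(f"read {self.id!r}: Phred scores outside [0, 93]")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentRecord:
    """A pairwise alignment between ``query_id`` and ``target_id``.

    ``ops`` is a run-length list of edit operations ``(op, length)`` with
    ``op`` one of ``"="`` (match), ``"X"`` (mismatch), ``"I"`` (insertion in
    the query, i.e. query-only bases) and ``"D"`` (deletion from the query,
    i.e. target-only bases).  Intervals are half-open on the plus strand of
    each sequence; for minus-strand alignments the query interval refers to
    the reverse-complemented query.
    """

    query_id: str
    target_id: str
    q_interval: tuple[int, int]
    t_interval: tuple[int, int]
    strand: str
    identity: float
    score: float
    ops: list[tuple[str, int]] = field(default_factory=list)

    @property
    def matches(self) -> int:
        return sum(n for op, n in self.ops if op == "=")

    @property
    def columns(self) -> int:
        return sum(n for _, n in self.ops)


# ---------------------------------------------------------------------------
# Phred codec


def phred_decode(qual_string: str) -> np.ndarray:
    """Decode a Sanger Phred+33 quality string into integer scores."""
    q = np.frombuffer(qual_string.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
    if len(q) and (q.min() < PHRED_MIN or q.max() > PHRED_MAX):
        raise ValueError("quality characters outside Phred+33 range [!, ~]")
    return q


def phred_encode(quals: Iterable[int]) -> str:
    q = np.asarray(list(quals), dtype=np.int16)
    if len(q) and (q.min() < PHRED_MIN or q.max() > PHRED_MAX):
        raise ValueError("Phred scores outside [0, 93]")
    return (q + 33).astype(np.uint8).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# FASTQ (4-line records, line-numbered errors per the I/O contract)


def parse_fastq(stream: TextIO | str, invalid: str = "error") -> list[ReadRecord]:
    """Parse Sanger Phred+33 FASTQ into ``ReadRecord`` objects.

    Accepts a text stream or a string.  Records must be 4 lines each; a
    truncated record or a seq/qual length mismatch raises
    :class:`FastqParseError` with the offending line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reads: list[ReadRecord] = []
    lineno = 0
    while True:
        header = stream.readline()
        if not header:
            break
        lineno += 1
        header = header.rstrip("\n")
        if not header:
            continue  # tolerate trailing blank lines
        if not header.startswith("@"):
            raise FastqParseError(f"expected '@' header, got {header[:20]!r}", lineno)
        block = [stream.readline() for _ in range(3)]
        if any(not line for line in block):
            raise FastqParseError("truncated FASTQ record", lineno)
        seq_line, plus_line, qual_line = (line.rstrip("\n") for line in block)
        if not plus_line.startswith("+"):
            raise FastqParseError("expected '+' separator line", lineno + 2)
        if len(seq_line) != len(qual_line):
            raise FastqParseError(
                f"sequence length {len(seq_line)} != quality length {len(qual_line)}",
                lineno + 3,
            )
        reads.append(
            ReadRecord(
                id=header[1:],
                seq=clean_seq(seq_line, invalid=invalid),
                quals=phred_decode(qual_line),
            )
        )
        lineno += 3
    return reads


def write_fastq(reads: Iterable[ReadRecord], handle: TextIO) -> None:
    for r in reads:
        handle.write(f"@{r.id}\n{r.seq}\n+\n{phred_encode(r.quals)}\n")


def format_fastq(reads: Iterable[ReadRecord]) -> str:
    buf = io.StringIO()
    write_fastq(reads, buf)
    return buf.getvalue()


def read_fastq(path) -> list[ReadRecord]:
    with open(path) as fh:
        return parse_fastq(fh)


# ---------------------------------------------------------------------------
# FASTA (via Biopython; wrapped at 80 columns on write)


def parse_fasta(handle: TextIO | str, invalid: str = "error") -> list[DnaSequence]:
    if isinstance(handle, str):
        handle = io.StringIO(handle)
    return [
        DnaSequence(id=rec.id, seq=clean_seq(str(rec.seq), invalid=invalid))
        for rec in SeqIO.parse(handle, "fasta")
    ]


def write_fasta(seqs: Iterable[DnaSequence], handle: TextIO, width: int = 80) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
    writer.write_file(records)


def read_fasta(path) -> list[DnaSequence]:
    with open(path) as fh:
        return parse_fasta(fh)


def save_fasta(seqs: Iterable[DnaSequence], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        write_fasta(seqs, fh, width=width)
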