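"""Per-read quality filtering and run summary statistics.

A read's quality is the basecaller convention: the per-base error
probabilities are averaged and converted back to the Phred scale,
``Q = -10*log10(mean_i 10^(-q_i/10))`` — not the arithmetic mean of the
per-base scores, which overstates accuracy on mixed-quality reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ReadRecord


@dataclass
class RunStats:
    """Summary of a quality-filtering pass.

    ``pass_fraction`` is a percentage of all input reads; mean quality and
    length are computed over the passing reads.
    """

    n_total: int
    n_passed: int
    pass_fraction: float
    mean_quality: float
    mean_length: float
    max_length: int

    def as_text(self) -> str:
        return (
            f"reads total\t{self.n_total}\n"
            f"reads passed\t{self.n_passed} ({self.pass_fraction:.1f}%)\n"
            f"mean read quality\t{self.mean_quality:.1f}\n"
            f"mean read length\t{self.mean_length:.0f}\n"
            f"max read length\t{self.max_length}\n"
        )


def mean_read_quality(quals: np.ndarray) -> float:
    """Error-probability-mean read quality on the Phred scale."""
    q = np.asarray(quals, dtype=float)
    if q.size == 0:
        raise ValueError("cannot compute quality of an empty read")
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


def phred_to_accuracy(q: float) -> float:
    """Percent base-call accuracy implied by a Phred score (Q10 -> 90%)."""
    if q < 0:
        raise ValueError("Phred score must be non-negative")
    return 100.0 * (1.0 - 10.0 ** (-q / 10.0))


def pass_fraction(n_passed: int, n_total: int) -> float:
    return 100.0 * n_passed / n_total if n_total else 0.0


def filter_reads(
    reads: list[ReadRecord], min_q: float = 10.0
) -> tuple[list[ReadRecord], RunStats]:
    """Keep reads whose mean quality is >= ``min_q`` (inclusive threshold)."""
    if min_q < 0:
        raise ValueError("min_q must be non-negative")
    passed = [r for r in reads if len(r) and mean_read_quality(r.quals) >= min_q]
    if passed:
        mean_q = float(np.mean([mean_read_quality(r.quals) for r in passed]))
        mean_len = float(np.mean([len(r) for r in passed]))
        max_len = max(len(r) for r in passed)
    else:
        mean_q = mean_len = 0.0
        max_len = 0
    stats = RunStats(
        n_total=len(reads),
        n_passed=len(passed),
        pass_fraction=pass_fraction(len(passed), len(reads)),
        mean_quality=mean_q,
        mean_length=mean_len,
        max_length=max_len,
    )
    return passed, stats
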