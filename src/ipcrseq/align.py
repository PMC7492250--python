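"""Pairwise alignment primitives.

Two engines back every alignment in the toolkit:

* an affine-gap Smith–Waterman (local) aligner, used wherever a scored
  local alignment is required (primer search, seed orientation, unitig
  matching, identity reports).  A gap of length L costs
  ``gap_open + (L - 1) * gap_extend``.
* edlib (edit-distance, banded) for large or unscored comparisons: overlap
  verification, read mapping and infix containment checks.

Default local scoring is (match +2, mismatch -3, gap_open -5, gap_extend -2).
"""

from __future__ import annotations

import re

import numpy as np
from numba import njit

import edlib

from .core import AlignmentRecord, reverse_complement

DEFAULT_SCORING = (2, -3, -5, -2)

# DP cell area above which exact local alignment falls back to an
# edlib-infix approximation (see local_align_large).
SW_CELL_CAP = 80_000_000

_ENCODE = np.zeros(128, dtype=np.int8)
for _i, _c in enumerate("ACGTN"):
    _ENCODE[ord(_c)] = _i


def _codes(s: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _sw_fill(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m = q.shape[0]
    n = t.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    ptr = np.zeros((m + 1, n + 1), np.uint8)
    F = np.full(n + 1, -(1 << 30), np.int32)
    neg = -(1 << 30)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        e = neg
        qi = q[i - 1]
        for j in range(1, n + 1):
            s = match if qi == t[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            e_open = H[i, j - 1] + gap_open
            e_ext = e + gap_extend
            if e_ext > e_open:
                e = e_ext
                ebit = np.uint8(4)
            else:
                e = e_open
                ebit = np.uint8(0)
            f_open = H[i - 1, j] + gap_open
            f_ext = F[j] + gap_extend
            if f_ext > f_open:
                f = f_ext
                fbit = np.uint8(8)
            else:
                f = f_open
                fbit = np.uint8(0)
            F[j] = f
            h = 0
            src = np.uint8(0)
            if diag > h:
                h = diag
                src = np.uint8(1)
            if e > h:
                h = e
                src = np.uint8(2)
            if f > h:
                h = f
                src = np.uint8(3)
            H[i, j] = h
            ptr[i, j] = src | ebit | fbit
            if h > best:
                best = h
                bi = i
                bj = j
    return H, ptr, best, bi, bj


def _traceback(q: str, t: str, ptr: np.ndarray, bi: int, bj: int):
    """Walk pointers from the best cell; returns (qs, qe, ts, te, ops)."""
    i, j = bi, bj
    raw: list[str] = []
    state = "H"
    while True:
        p = ptr[i, j]
        if state == "H":
            src = p & 3
            if src == 0:
                break
            if src == 1:
                raw.append("=" if q[i - 1] == t[j - 1] else "X")
                i -= 1
                j -= 1
            elif src == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in query: consumes target (op D)
            raw.append("D")
            ext = ptr[i, j] & 4
            j -= 1
            if not ext:
                state = "H"
        else:  # F: gap in target: consumes query (op I)
            raw.append("I")
            ext = ptr[i, j] & 8
            i -= 1
            if not ext:
                state = "H"
    raw.reverse()
    return i, bi, j, bj, run_length(raw)


def run_length(ops: list[str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


def local_align(
    query: str,
    target: str,
    scoring: tuple[int, int, int, int] = DEFAULT_SCORING,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentRecord:
    """Optimal Smith–Waterman local alignment (plus strand only).

    Callers needing minus-strand search align the reverse complement of the
    query themselves.  If no cell scores positively an empty alignment with
    score 0 is returned.
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    match, mismatch, gap_open, gap_extend = scoring
    if (len(query) + 1) * (len(target) + 1) > SW_CELL_CAP:
        return local_align_large(query, target, scoring, query_id, target_id)
    H, ptr, best, bi, bj = _sw_fill(
        _codes(query), _codes(target), match, mismatch, gap_open, gap_extend
    )
    if best <= 0:
        return AlignmentRecord(query_id, target_id, (0, 0), (0, 0), "+", 0.0, 0.0, [])
    qs, qe, ts, te, ops = _traceback(query, target, ptr, bi, bj)
    matches = sum(n for op, n in ops if op == "=")
    cols = sum(n for _, n in ops)
    return AlignmentRecord(
        query_id, target_id, (qs, qe), (ts, te), "+",
        matches / cols if cols else 0.0, float(best), ops,
    )


def best_local_align(
    query: str,
    target: str,
    scoring: tuple[int, int, int, int] = DEFAULT_SCORING,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentRecord:
    """Best local alignment over both strands (minus = revcomp of query)."""
    fwd = local_align(query, target, scoring, query_id, target_id)
    rev = local_align(reverse_complement(query), target, scoring, query_id, target_id)
    if rev.score > fwd.score:
        rev.strand = "-"
        return rev
    return fwd


# ---------------------------------------------------------------------------
# edlib helpers


def edit_distance(a: str, b: str, mode: str = "NW", k: int = -1) -> int:
    """Edit distance between ``a`` and ``b`` (-1 if it exceeds ``k``)."""
    return edlib.align(a, b, mode=mode, k=k)["editDistance"]


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def edlib_ops(query: str, target: str, mode: str = "NW") -> tuple[int, int, list[tuple[str, int]]]:
    """Align with edlib and return ``(t_start, t_end, ops)``.

    ``ops`` use the same =/X/I/D vocabulary as :class:`AlignmentRecord`
    (I = query-only bases, D = target-only bases); edlib's extended CIGAR
    follows the same convention.
    """
    res = edlib.align(query, target, mode=mode, task="path")
    ts, te = res["locations"][0]
    ts = ts or 0
    ops = [(op, int(n)) for n, op in _CIGAR_RE.findall(res["cigar"])]
    return ts, te + 1, ops


def infix_identity(query: str, target: str) -> tuple[float, tuple[int, int]]:
    """Identity of the best infix (query-global) alignment of query in target."""
    res = edlib.align(query, target, mode="HW", task="locations")
    d = res["editDistance"]
    ts, te = res["locations"][0]
    cols = max(len(query), te + 1 - ts)
    return 1.0 - d / cols, (ts, te + 1)


def local_align_large(
    query: str,
    target: str,
    scoring: tuple[int, int, int, int] = DEFAULT_SCORING,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentRecord:
    """Approximate local alignment for pairs too large for the exact DP.

    The shorter sequence is infix-aligned into the longer with edlib and the
    resulting column string is trimmed to its maximal-scoring contiguous
    segment under the supplied scoring — the natural local-alignment analogue
    for near-contained sequences (the only large case the pipeline meets).
    """
    flipped = len(query) > len(target)
    a, b = (target, query) if flipped else (query, target)
    ts, te, ops = edlib_ops(a, b, mode="HW")
    match, mismatch, gap_open, gap_extend = scoring
    # expand runs into per-column scores, then maximal scoring subarray
    cols: list[tuple[str, int]] = []
    for op, n in ops:
        for i in range(n):
            if op == "=":
                cols.append((op, match))
            elif op == "X":
                cols.append((op, mismatch))
            else:
                cols.append((op, gap_open if i == 0 else gap_extend))
    best = cur = 0
    best_range = (0, 0)
    start = 0
    for i, (_, s) in enumerate(cols):
        cur += s
        if cur <= 0:
            cur = 0
            start = i + 1
        elif cur > best:
            best = cur
            best_range = (start, i + 1)
    if best <= 0:
        return AlignmentRecord(query_id, target_id, (0, 0), (0, 0), "+", 0.0, 0.0, [])
    lo, hi = best_range
    # convert trimmed columns back to coordinates on a (query frame) and b
    qa = 0
    tb = ts
    qs = q_end = t_start = t_end = None
    trimmed: list[str] = []
    for i, (op, _) in enumerate(cols):
        if i == lo:
            qs, t_start = qa, tb
        if i == hi:
            break
        if lo <= i:
            trimmed.append(op)
        if op in ("=", "X"):
            qa += 1
            tb += 1
        elif op == "I":
            qa += 1
        else:
            tb += 1
    q_end, t_end = qa, tb
    ops_rl = run_length(trimmed)
    matches = sum(n for op, n in ops_rl if op == "=")
    ncols = sum(n for _, n in ops_rl)
    q_iv, t_iv = (qs, q_end), (t_start, t_end)
    if flipped:
        q_iv, t_iv = t_iv, q_iv
        ops_rl = [("D" if op == "I" else "I" if op == "D" else op, n) for op, n in ops_rl]
    return AlignmentRecord(
        query_id, target_id, q_iv, t_iv, "+",
        matches / ncols if ncols else 0.0, float(best), ops_rl,
    )
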