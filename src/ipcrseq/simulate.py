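"""Ground-truthed simulation of the targeted inverse-PCR protocol.

The wet-lab geometry being emulated: genomic DNA carrying a transgene
insertion is sheared into ~6 kb fragments, the fragments are end-repaired
and self-ligated into circles, remaining linear molecules are degraded by
exonuclease, and an outward-facing primer pair anchored in the p35S
screening element amplifies every circle that contains the element.  The
amplicons — each a rotation of its source fragment minus the short
inter-primer gap — are then read on a nanopore-style instrument at ~6%
per-base error.

Every stage records its ground truth (source intervals, circularization
junction positions, per-read source coordinates) so the downstream pipeline
can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import ReadRecord, reverse_complement

#: the two outward-facing inverse-PCR primers anchored in p35S
P35S_FORWARD = "CAATCCACTTGCTTTGAAGACG"
P35S_REVERSE = "AATCCCACTATCCTTCGCAAGA"

_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass
class Locus:
    """A plant locus with an inserted construct: flank5 + transgene + flank3."""

    seq: str
    junction5: int
    junction3: int
    element_annotations: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    def element(self, name: str) -> tuple[int, int]:
        for n, iv in self.element_annotations:
            if n == name:
                return iv
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CircularMolecule:
    """A sheared fragment after (attempted) circularization.

    The sequence is stored linearized at the shear junction: position 0 is
    the first base after the ligation point, so the junction sits between
    the last and first stored base.
    """

    id: str
    seq: str
    origin: tuple[str, int, int]  # (source name, start, end) on the source
    shear_junction_offset: int = 0
    circular: bool = True

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Amplicon:
    """Linear inverse-PCR product of one circle.

    ``truth_segments`` maps amplicon coordinates back to the source sequence
    as an ordered list of plus-strand intervals; two segments means the
    amplicon crosses the molecule-specific circularization junction at
    ``shear_junction_pos``.
    """

    id: str
    seq: str
    source_circle: str
    primer_f_interval: tuple[int, int]
    primer_r_interval: tuple[int, int]
    shear_junction_pos: Optional[int] = None
    truth_segments: list[tuple[str, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ErrorModel:
    """Per-base nanopore-style error model.

    Defaults put the expected per-base accuracy at ~94% (substitution 3%,
    insertion 1.5%, deletion 1.5%) with a mean read length of 1,879 bp,
    matching a short nanopore amplicon run after in-prep shearing.
    """

    sub_rate: float = 0.03
    ins_rate: float = 0.015
    del_rate: float = 0.015
    mean_read_len: float = 1879.0
    read_len_sd: float = 1200.0

    def __post_init__(self) -> None:
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(not (0 <= r < 1) for r in rates) or sum(rates) >= 0.5:
            raise ValueError("error rates must be in [0,1) and sum below 0.5")

    @property
    def total_error(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


def make_p35s_element(
    rng: np.random.Generator,
    length: int = 350,
    gap: int = 80,
    r_offset: int = 100,
) -> str:
    """Synthesize a p35S-like screening element carrying both primer sites.

    Layout on the plus strand: filler, reverse complement of the reverse
    primer (the reverse primer anneals here and extends leftward), an
    inter-primer gap (the short region a conventional p35S qPCR assay would
    amplify — it is *not* covered by the inverse-PCR product), then the
    forward primer extending rightward.
    """
    f_offset = r_offset + len(P35S_REVERSE) + gap
    if f_offset + len(P35S_FORWARD) > length:
        raise ValueError("element too short for primer layout")
    filler = random_dna(rng, length)
    elem = (
        filler[:r_offset]
        + reverse_complement(P35S_REVERSE)
        + filler[r_offset + len(P35S_REVERSE) : f_offset]
        + P35S_FORWARD
        + filler[f_offset + len(P35S_FORWARD) :]
    )
    assert len(elem) == length
    return elem


def build_locus(
    flank5: str,
    transgene: str,
    flank3: str,
    p35s: str,
) -> Locus:
    """Concatenate flank5 + transgene + flank3 and lift the p35S annotation.

    The transgene must contain the p35S element exactly once (the anchor is
    otherwise ambiguous).
    """
    n = transgene.count(p35s)
    if n != 1:
        raise ValueError(f"p35S element found {n} times in transgene, need exactly 1")
    j5 = len(flank5)
    j3 = j5 + len(transgene)
    off = j5 + transgene.index(p35s)
    return Locus(
        seq=flank5 + transgene + flank3,
        junction5=j5,
        junction3=j3,
        element_annotations=[("p35S", (off, off + len(p35s)))],
    )


def random_locus(
    rng: np.random.Generator,
    flank5_len: int = 3000,
    transgene_len: int = 6168,
    flank3_len: int = 3000,
    p35s_offset: int = 2750,
    p35s_len: int = 350,
) -> tuple[Locus, str]:
    """Random locus with a p35S element embedded in the transgene.

    Returns ``(locus, p35s_element)``; the element doubles as the pipeline's
    known seed sequence.
    """
    elem = make_p35s_element(rng, length=p35s_len)
    tg = random_dna(rng, transgene_len)
    if p35s_offset + p35s_len > transgene_len:
        raise ValueError("p35S element does not fit in the transgene")
    tg = tg[:p35s_offset] + elem + tg[p35s_offset + p35s_len :]
    locus = build_locus(random_dna(rng, flank5_len), tg, random_dna(rng, flank3_len), elem)
    return locus, elem


def shear_circularize(
    background: str,
    locus: Locus,
    n_molecules: int,
    frag_mean: float = 6000.0,
    frag_sd: float = 600.0,
    p_circularize: float = 0.9,
    exo_efficiency: float = 0.99,
    rng: np.random.Generator | int = 0,
    target_fraction: float = 0.1,
) -> list[CircularMolecule]:
    """Shear, circularize and exonuclease-select a pool of molecules.

    Fragment lengths are Normal(frag_mean, frag_sd) truncated to
    [500, 3*frag_mean].  ``target_fraction`` of molecules are drawn from the
    locus; the rest come from the background (non-target) sequence and model
    the genomic majority that never amplifies.  Linear (uncircularized)
    molecules survive the exonuclease only with probability
    ``1 - exo_efficiency``.
    """
    if frag_mean <= 0:
        raise ValueError("frag_mean must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    out: list[CircularMolecule] = []
    for i in range(n_molecules):
        from_target = rng.random() < target_fraction
        name, src = ("locus", locus.seq) if from_target else ("background", background)
        length = int(round(np.clip(rng.normal(frag_mean, frag_sd), 500, 3 * frag_mean)))
        length = min(length, len(src))
        start = int(rng.integers(0, len(src) - length + 1))
        circular = rng.random() < p_circularize
        if not circular and rng.random() < exo_efficiency:
            continue  # degraded
        out.append(
            CircularMolecule(
                id=f"mol{i}",
                seq=src[start : start + length],
                origin=(name, start, start + length),
                shear_junction_offset=0,
                circular=circular,
            )
        )
    return out


def inverse_pcr(
    circle: CircularMolecule,
    forward: str = P35S_FORWARD,
    reverse: str = P35S_REVERSE,
) -> Optional[Amplicon]:
    """Amplify a circle with an outward-facing primer pair, if possible.

    Primer sites are located by exact match on the circular sequence (both
    strands).  When both sites are present in outward configuration the
    product is the arc from the start of the forward-primer site, the long
    way around the circle, to the (plus-strand) end of the reverse-primer
    site — i.e. the whole circle minus the open inter-primer gap, with the
    primer sites included at both ends.  Linear molecules and circles
    missing a site yield ``None``.
    """
    if not circle.circular:
        return None
    L = len(circle.seq)
    if L < len(forward) + len(reverse):
        return None
    for strand, seq in (("+", circle.seq), ("-", reverse_complement(circle.seq))):
        doubled = seq + seq
        r_site = reverse_complement(reverse)
        f_hits = _circular_find(doubled, forward, L)
        r_hits = _circular_find(doubled, r_site, L)
        if len(f_hits) != 1 or len(r_hits) != 1:
            continue
        f = f_hits[0]
        end = r_hits[0] + len(r_site)
        if end <= f:
            end += L
        if end - f > L:
            continue  # primer sites overlap-wrap: not an amplifiable configuration
        amp_seq = doubled[f:end]
        alen = end - f
        # shear junction lives between stored positions L-1 and 0
        sj = None
        if strand == "+":
            if 0 < L - f < alen:
                sj = L - f
        else:
            # on the minus strand the junction maps to position f' where the
            # rc coordinate crosses the origin
            if 0 < L - f < alen:
                sj = L - f
        segs = _truth_segments(circle, f, alen, strand)
        return Amplicon(
            id=f"amp_{circle.id}",
            seq=amp_seq,
            source_circle=circle.id,
            primer_f_interval=(0, len(forward)),
            primer_r_interval=(alen - len(r_site), alen),
            shear_junction_pos=sj,
            truth_segments=segs,
        )
    return None


def _circular_find(doubled: str, pattern: str, L: int) -> list[int]:
    hits = []
    start = 0
    while True:
        i = doubled.find(pattern, start)
        if i == -1 or i >= L:
            break
        hits.append(i)
        start = i + 1
    return hits


def _truth_segments(circle: CircularMolecule, f: int, alen: int, strand: str):
    """Map amplicon coordinates to source-sequence plus-strand intervals."""
    name, s0, _e0 = circle.origin
    L = len(circle.seq)
    segs = []
    if strand == "+":
        first = min(alen, L - f)
        segs.append((name, s0 + f, s0 + f + first))
        if alen > first:
            segs.append((name, s0, s0 + alen - first))
    else:
        # amplicon lives on the minus strand of the stored circle; express
        # the covered plus-strand intervals in traversal order
        first = min(alen, L - f)
        a = L - (f + first)
        segs.append((name, s0 + a, s0 + a + first))
        if alen > first:
            rest = alen - first
            segs.append((name, s0 + L - rest, s0 + L))
    return segs


def simulate_reads(
    amplicons: list[Amplicon],
    model: ErrorModel,
    depth_target: float | None = 400.0,
    n_reads: int | None = None,
    rng: np.random.Generator | int = 0,
    quality_jitter: float = 1.5,
) -> list[ReadRecord]:
    """Sample noisy reads from random subintervals of the amplicon pool.

    Each read picks an amplicon uniformly (PCR copy number is taken as
    uniform across circles), a Normal(mean_read_len, read_len_sd) length
    clipped to the amplicon, a random strand, then applies per-base
    substitutions/insertions/deletions at the model rates.  Qualities are
    drawn as round(-10*log10(total error rate)) with Gaussian jitter.
    ``depth_target`` is fold coverage of the locus region spanned by the
    amplicon pool; ``n_reads`` overrides it directly.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if not amplicons:
        import warnings

        warnings.warn("no amplicons to sequence; returning no reads")
        return []
    if n_reads is None:
        if depth_target is None or depth_target <= 0:
            raise ValueError("need a positive depth_target or an explicit n_reads")
        lo = min(s for a in amplicons for (_, s, _) in a.truth_segments)
        hi = max(e for a in amplicons for (_, _, e) in a.truth_segments)
        n_reads = int(round(depth_target * (hi - lo) / model.mean_read_len))
    reads: list[ReadRecord] = []
    q_center = -10.0 * np.log10(max(model.total_error, 1e-6))
    for i in range(n_reads):
        amp = amplicons[int(rng.integers(0, len(amplicons)))]
        length = int(round(rng.normal(model.mean_read_len, model.read_len_sd)))
        length = int(np.clip(length, 100, len(amp)))
        # the sampled window may overhang either amplicon end (library-prep
        # shearing leaves end-anchored pieces); clip to the amplicon, keeping
        # at least 100 bp inside, so reads cover the primer-bearing ends at a
        # realistic rate
        s0 = int(rng.integers(-(length - 100), len(amp) - 100 + 1))
        start = max(0, s0)
        end = min(len(amp), s0 + length)
        length = end - start
        strand = "+" if rng.random() < 0.5 else "-"
        template = amp.seq[start : start + length]
        if strand == "-":
            template = reverse_complement(template)
        seq, quals = _apply_errors(template, model, rng, q_center, quality_jitter)
        if not seq:
            continue
        reads.append(
            ReadRecord(
                id=f"read{i}_{amp.id}_{start}_{start + length}_{strand}",
                seq=seq,
                quals=quals,
                truth=(amp.id, (start, start + length), strand),
            )
        )
    return reads


def _apply_errors(template, model, rng, q_center, jitter):
    n = len(template)
    out: list[str] = []
    # single vectorized draw per template keeps the rng cheap and reproducible
    r = rng.random((n, 2))
    subs = rng.integers(1, 4, size=n)
    ins_bases = rng.integers(0, 4, size=n)
    for i, base in enumerate(template):
        if r[i, 0] < model.del_rate:
            pass  # deleted
        else:
            if r[i, 0] < model.del_rate + model.sub_rate:
                base = _BASES[(("ACGT".index(base) if base != "N" else 0) + subs[i]) % 4]
            out.append(base)
        if r[i, 1] < model.ins_rate:
            out.append(_BASES[ins_bases[i]])
    seq = "".join(out)
    quals = np.clip(
        np.round(q_center + rng.normal(0.0, jitter, size=len(seq))), 2, 41
    ).astype(np.int16)
    return seq, quals


# ---------------------------------------------------------------------------
# Run orchestration


@dataclass
class SimulationRun:
    locus: Locus
    p35s: str
    background: str
    molecules: list[CircularMolecule]
    amplicons: list[Amplicon]
    reads: list[ReadRecord]

    @property
    def covered_interval(self) -> tuple[int, int]:
        """Locus interval reachable by the amplicon pool (the truth span)."""
        starts = [s for a in self.amplicons for (n, s, _) in a.truth_segments if n == "locus"]
        ends = [e for a in self.amplicons for (n, _, e) in a.truth_segments if n == "locus"]
        return (min(starts), max(ends))


def simulate_run(
    seed: int = 0,
    flank5_len: int = 3000,
    transgene_len: int = 6168,
    flank3_len: int = 3000,
    p35s_offset: int = 2750,
    p35s_len: int = 350,
    background_len: int = 60000,
    n_molecules: int = 20000,
    target_fraction: float = 0.1,
    frag_mean: float = 6000.0,
    frag_sd: float = 600.0,
    p_circularize: float = 0.9,
    exo_efficiency: float = 0.99,
    model: ErrorModel | None = None,
    depth_target: float | None = None,
    n_reads: int | None = 2000,
) -> SimulationRun:
    """One full synthetic run: locus -> circles -> amplicons -> reads."""
    rng = np.random.default_rng(seed)
    locus, elem = random_locus(
        rng, flank5_len, transgene_len, flank3_len, p35s_offset, p35s_len
    )
    background = random_dna(rng, background_len)
    molecules = shear_circularize(
        background, locus, n_molecules, frag_mean, frag_sd,
        p_circularize, exo_efficiency, rng, target_fraction,
    )
    amplicons = [a for a in (inverse_pcr(m) for m in molecules) if a is not None]
    model = model or ErrorModel()
    reads = simulate_reads(amplicons, model, depth_target=depth_target, n_reads=n_reads, rng=rng)
    return SimulationRun(locus, elem, background, molecules, amplicons, reads)


def write_truth_bed(run: SimulationRun, handle) -> None:
    """BED4 of read truth intervals plus junction features."""
    for r in run.reads:
        if r.truth is None:
            continue
        amp_id, (s, e), strand = r.truth
        handle.write(f"{amp_id}\t{s}\t{e}\t{r.id};{strand}\n")
    for a in run.amplicons:
        if a.shear_junction_pos is not None:
            handle.write(f"{a.id}\t{a.shear_junction_pos}\t{a.shear_junction_pos + 1}\tshear_junction\n")
    j5 = run.locus.junction5
    handle.write(f"locus\t{j5}\t{j5 + 1}\tjunction5\n")
    j3 = run.locus.junction3
    handle.write(f"locus\t{j3}\t{j3 + 1}\tjunction3\n")
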