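import numpy as np
import pytest

from ipcrseq.core import ReadRecord, reverse_complement
from ipcrseq.draft import (
    Contig,
    contigs_same,
    find_overlaps,
    greedy_assemble,
    iterate_draft,
    orient_contig,
    pick_two_longest_distinct,
)
from ipcrseq.simulate import random_dna


def read_from(seq, i=0):
    return ReadRecord(id=f"r{i:03d}", seq=seq, quals=np.full(len(seq), 12, dtype=np.int16))


def tiling_reads(source, read_len=1000, step=500):
    reads = []
    for i, s in enumerate(range(0, max(1, len(source) - read_len + 1), step)):
        reads.append(read_from(source[s : s + read_len], i))
    return reads


class TestFindOverlaps:
    def test_noiseless_suffix_prefix_overlap(self, rng):
        src = random_dna(rng, 2500)
        a, b = read_from(src[:1500], 0), read_from(src[1000:], 1)
        ovls = find_overlaps([a, b])
        assert len(ovls) == 1
        rec = ovls[0]
        assert rec.strand == "+"
        assert rec.identity == 1.0
        assert abs(rec.overlap_len - 500) <= 5
        assert abs(rec.offset - 1000) <= 5

    def test_random_reads_no_overlap(self, rng):
        a, b = read_from(random_dna(rng, 1500), 0), read_from(random_dna(rng, 1500), 1)
        assert find_overlaps([a, b]) == []

    def test_minus_strand_containment(self, rng):
        src = random_dna(rng, 1500)
        a = read_from(src, 0)
        b = read_from(reverse_complement(src[400:1000]), 1)
        ovls = find_overlaps([a, b])
        assert len(ovls) == 1
        assert ovls[0].strand == "-"
        assert abs(ovls[0].overlap_len - 600) <= 5


class TestGreedyAssemble:
    def test_noiseless_tiling_reconstructs_source(self, rng):
        src = random_dna(rng, 5000)
        reads = tiling_reads(src)
        contigs = greedy_assemble(reads, find_overlaps(reads))
        big = [c for c in contigs if c.provenance["n_reads"] > 1]
        assert len(big) == 1
        assert big[0].seq == src

    def test_no_overlaps_short_reads_filtered(self, rng):
        reads = [read_from(random_dna(rng, 600), i) for i in range(4)]
        contigs = greedy_assemble(reads, [])
        assert contigs == []  # singletons under 1000 bp are not reported

    def test_disjoint_sources_give_separate_contigs(self, rng):
        s1, s2 = random_dna(rng, 3000), random_dna(rng, 3000)
        reads = tiling_reads(s1) + [
            read_from(r.seq, 100 + i) for i, r in enumerate(tiling_reads(s2))
        ]
        contigs = greedy_assemble(reads, find_overlaps(reads))
        big = sorted((c for c in contigs if c.provenance["n_reads"] > 1), key=lambda c: c.seq)
        assert len(big) == 2
        assert {c.seq for c in big} == {s1, s2}


class TestIterateDraft:
    def test_iteration_count_and_determinism(self, rng):
        src = random_dna(rng, 4000)
        reads = tiling_reads(src, 1200, 300)
        a = iterate_draft(reads, n=8, iterations=3, rng=5)
        b = iterate_draft(reads, n=8, iterations=3, rng=5)
        assert len(a) == 3
        assert [[c.seq for c in coll] for coll in a] == [[c.seq for c in coll] for coll in b]

    def test_oversized_subsample_uses_all(self, rng):
        src = random_dna(rng, 3000)
        reads = tiling_reads(src)
        with pytest.warns(UserWarning):
            colls = iterate_draft(reads, n=1000, iterations=1, rng=0)
        assert len(colls) == 1


class TestPickTwoLongest:
    def contig(self, seq, cid, n_reads=5):
        return Contig(id=cid, seq=seq, provenance={"n_reads": n_reads})

    def test_two_distinct_sources(self, rng):
        x = self.contig(random_dna(rng, 5000), "x")
        y = self.contig(random_dna(rng, 4000), "y")
        picked = pick_two_longest_distinct([[x] * 3, [y] * 3])
        assert [c.id for c in picked] == ["x", "y"]

    def test_all_fragments_of_one_sequence(self, rng):
        src = random_dna(rng, 5000)
        frags = [self.contig(src[: 3000 + 200 * i], f"f{i}") for i in range(4)]
        with pytest.warns(UserWarning):
            picked = pick_two_longest_distinct([frags])
        assert len(picked) == 1

    def test_mutated_copy_treated_as_same(self, rng):
        src = random_dna(rng, 4000)
        mutated = list(src)
        for p in rng.choice(len(src), size=40, replace=False):  # 1% divergence
            mutated[p] = "ACGT"[("ACGT".index(mutated[p]) + 1) % 4]
        x = self.contig(src, "x")
        x2 = self.contig("".join(mutated), "y")
        z = self.contig(random_dna(rng, 3500), "z")
        assert contigs_same(x, x2)
        picked = pick_two_longest_distinct([[x, x2, z]])
        assert [c.id for c in picked] == ["x", "z"]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pick_two_longest_distinct([[]])


class TestOrientContig:
    def test_forward_seed_unchanged(self, rng):
        seed = random_dna(rng, 300)
        seq = random_dna(rng, 1000) + seed + random_dna(rng, 200)
        c = Contig(id="c", seq=seq)
        out = orient_contig(c, seed)
        assert out.seq == seq
        assert out.oriented
        assert out.seed_interval == (1000, 1300)

    def test_reverse_seed_flips(self, rng):
        seed = random_dna(rng, 300)
        seq = random_dna(rng, 1000) + seed + random_dna(rng, 200)
        c = Contig(id="c", seq=reverse_complement(seq))
        out = orient_contig(c, seed)
        assert out.seq == seq

    def test_orientation_involutive(self, rng):
        seed = random_dna(rng, 300)
        seq = random_dna(rng, 800) + seed + random_dna(rng, 400)
        a = orient_contig(Contig(id="c", seq=seq), seed)
        b = orient_contig(Contig(id="c", seq=reverse_complement(seq)), seed)
        assert a.seq == b.seq

    def test_seed_absent_raises(self, rng):
        with pytest.raises(ValueError, match="seed not found"):
            orient_contig(Contig(id="c", seq=random_dna(rng, 2000)), random_dna(rng, 300))

    def test_short_seed_rejected(self, rng):
        with pytest.raises(ValueError):
            orient_contig(Contig(id="c", seq=random_dna(rng, 500)), "ACGT")
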