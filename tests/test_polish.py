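import numpy as np
import pytest

import edlib

from ipcrseq.core import ReadRecord, reverse_complement
from ipcrseq.polish import (
    DepthProfile,
    depth_stats,
    locate_junction,
    map_reads,
    percent_identity,
    pileup_consensus,
)
from ipcrseq.simulate import random_dna


def read_from(seq, i=0):
    return ReadRecord(id=f"r{i}", seq=seq, quals=np.full(len(seq), 12, dtype=np.int16))


def tiling_reads(source, read_len=600, step=150):
    return [
        read_from(source[s : s + read_len], i)
        for i, s in enumerate(range(0, len(source) - read_len + 1, step))
    ]


class TestMapReads:
    def test_exact_substring_full_match(self, rng):
        ref = random_dna(rng, 3000)
        recs = map_reads([read_from(ref[500:1500])], ref)
        assert len(recs) == 1
        assert recs[0].identity == 1.0
        assert recs[0].t_interval == (500, 1500)
        assert recs[0].strand == "+"

    def test_random_read_unmapped(self, rng):
        ref = random_dna(rng, 3000)
        assert map_reads([read_from(random_dna(rng, 800))], ref) == []

    def test_minus_strand_read(self, rng):
        ref = random_dna(rng, 3000)
        recs = map_reads([read_from(reverse_complement(ref[1000:1800]))], ref)
        assert len(recs) == 1
        assert recs[0].strand == "-"
        assert recs[0].t_interval == (1000, 1800)

    def test_empty_reference_rejected(self, rng):
        with pytest.raises(ValueError):
            map_reads([], "")


class TestPileupConsensus:
    def test_agreeing_reads_are_a_fixed_point(self, rng):
        ref = random_dna(rng, 2000)
        reads = tiling_reads(ref)
        aligns = map_reads(reads, ref)
        polished, profile = pileup_consensus(aligns, reads, ref, min_end_depth=1)
        assert polished == ref

    def test_majority_substitution_wins(self, rng):
        ref = random_dna(rng, 1200)
        corrupt = list(ref)
        corrupt[600] = "A" if ref[600] != "A" else "C"
        corrupt = "".join(corrupt)
        reads = tiling_reads(ref)
        aligns = map_reads(reads, corrupt)
        polished, _ = pileup_consensus(aligns, reads, corrupt, min_end_depth=1)
        assert polished == ref

    def test_planted_errors_fully_corrected(self, rng):
        # 10 substitutions planted in the reference; 100 noiseless reads
        # restore the truth exactly (edit distance reaches 0)
        truth = random_dna(rng, 2000)
        corrupt = list(truth)
        for p in rng.choice(np.arange(100, 1900), size=10, replace=False):
            corrupt[p] = "ACGT"[("ACGT".index(corrupt[p]) + 2) % 4]
        corrupt = "".join(corrupt)
        reads = [
            read_from(truth[s : s + 500], i)
            for i, s in enumerate(rng.integers(0, 1500, size=100))
        ]
        aligns = map_reads(reads, corrupt)
        polished, _ = pileup_consensus(aligns, reads, corrupt, min_end_depth=1)
        assert polished == truth
        assert edlib.align(polished, truth, mode="NW")["editDistance"] == 0

    def test_indel_errors_corrected(self, rng):
        truth = random_dna(rng, 1500)
        corrupt = truth[:400] + truth[401:900] + "GG" + truth[900:]  # del + ins
        reads = tiling_reads(truth, 500, 100)
        aligns = map_reads(reads, corrupt)
        polished, _ = pileup_consensus(aligns, reads, corrupt, min_end_depth=1)
        assert polished == truth

    def test_polishing_is_contraction_on_noiseless_reads(self, rng):
        truth = random_dna(rng, 1500)
        corrupt = list(truth)
        for p in rng.choice(np.arange(50, 1450), size=15, replace=False):
            corrupt[p] = "ACGT"[("ACGT".index(corrupt[p]) + 1) % 4]
        ref = "".join(corrupt)
        reads = tiling_reads(truth, 500, 100)
        dist = edlib.align(ref, truth, mode="NW")["editDistance"]
        for _ in range(3):
            aligns = map_reads(reads, ref)
            new_ref, _ = pileup_consensus(aligns, reads, ref, max_rounds=1, min_end_depth=1)
            new_dist = edlib.align(new_ref, truth, mode="NW")["editDistance"]
            assert new_dist <= dist
            ref, dist = new_ref, new_dist
        assert dist == 0

    def test_no_alignments_rejected(self, rng):
        with pytest.raises(ValueError):
            pileup_consensus([], [], random_dna(rng, 100))


class TestDepthStats:
    def test_uniform(self):
        p = DepthProfile(depth=np.full(100, 10), base_counts={})
        assert depth_stats(p) == (10, 10, 10.0)

    def test_small_example(self):
        p = DepthProfile(depth=np.array([1, 2, 3]), base_counts={})
        assert depth_stats(p) == (1, 3, 2.0)

    def test_depth_mass_conservation(self, rng):
        ref = random_dna(rng, 1500)
        reads = tiling_reads(ref)
        aligns = map_reads(reads, ref)
        _, profile = pileup_consensus(aligns, reads, ref, min_end_depth=1)
        aligned_bases = sum(
            sum(n for op, n in a.ops if op in ("=", "X", "D")) for a in aligns
        )
        assert int(profile.depth.sum()) == aligned_bases

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            depth_stats(DepthProfile(depth=np.array([]), base_counts={}))


class TestPercentIdentity:
    def test_identical_sequences(self, rng):
        s = random_dna(rng, 3304)
        ident, span = percent_identity(s, s)
        assert ident == 100.0
        assert span == 3304

    def test_one_mismatch_in_thousand(self, rng):
        s = random_dna(rng, 1000)
        t = s[:500] + ("A" if s[500] != "A" else "C") + s[501:]
        ident, span = percent_identity(s, t)
        assert ident == pytest.approx(99.9, abs=0.01)

    def test_disjoint_sequences_give_zero(self, rng):
        with pytest.warns(UserWarning):
            ident, span = percent_identity(random_dna(rng, 500), random_dna(rng, 500))
        assert (ident, span) == (0.0, 0)

    def test_symmetric_in_arguments(self, rng):
        a = random_dna(rng, 2000)
        b = a[300:1700]
        i1, s1 = percent_identity(a, b)
        i2, s2 = percent_identity(b, a)
        assert i1 == pytest.approx(i2)


class TestLocateJunction:
    def test_exact_boundary(self, rng):
        plant = random_dna(rng, 3000)
        transgene = random_dna(rng, 6000)
        call = locate_junction(plant + transgene, plant, transgene)
        assert call is not None
        assert call.position == 3000

    def test_missing_transgene_gives_none(self, rng):
        plant = random_dna(rng, 3000)
        assert locate_junction(plant, plant, random_dna(rng, 2000)) is None
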