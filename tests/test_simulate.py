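import numpy as np
import pytest

import edlib

from ipcrseq.core import reverse_complement
from ipcrseq.simulate import (
    Amplicon,
    CircularMolecule,
    ErrorModel,
    P35S_FORWARD,
    P35S_REVERSE,
    build_locus,
    inverse_pcr,
    make_p35s_element,
    random_dna,
    shear_circularize,
    simulate_reads,
    simulate_run,
)


@pytest.fixture(scope="module")
def element():
    return make_p35s_element(np.random.default_rng(0))


class TestBuildLocus:
    def test_junction_arithmetic(self, rng, element):
        tg = random_dna(rng, 6168 - len(element)) + element
        locus = build_locus(random_dna(rng, 3000), tg, random_dna(rng, 3000), element)
        assert len(locus.seq) == 12168
        assert locus.junction5 == 3000
        assert locus.junction3 == 9168
        p0, p1 = locus.element("p35S")
        assert locus.junction5 <= p0 < p1 <= locus.junction3

    def test_empty_flank3_boundary(self, rng, element):
        tg = element + random_dna(rng, 500)
        locus = build_locus(random_dna(rng, 100), tg, "", element)
        assert locus.junction3 == len(locus.seq)

    def test_missing_or_duplicate_element_rejected(self, rng, element):
        with pytest.raises(ValueError):
            build_locus("ACGT", random_dna(rng, 1000), "ACGT", element)
        with pytest.raises(ValueError):
            build_locus("ACGT", element + element, "ACGT", element)


class TestShearCircularize:
    def test_all_circular_at_limit(self, rng, element):
        tg = element + random_dna(rng, 1000)
        locus = build_locus(random_dna(rng, 500), tg, random_dna(rng, 500), element)
        mols = shear_circularize(random_dna(rng, 5000), locus, 200, 1000, 100, 1.0, 1.0, rng)
        assert len(mols) == 200 and all(m.circular for m in mols)

    def test_no_circularization_full_exonuclease(self, rng, element):
        tg = element + random_dna(rng, 1000)
        locus = build_locus(random_dna(rng, 500), tg, random_dna(rng, 500), element)
        mols = shear_circularize(random_dna(rng, 5000), locus, 200, 1000, 100, 0.0, 1.0, rng)
        assert mols == []

    def test_fragment_length_distribution(self, element):
        rng = np.random.default_rng(11)
        tg = element + random_dna(rng, 500)
        locus = build_locus(random_dna(rng, 100), tg, random_dna(rng, 100), element)
        mols = shear_circularize(
            random_dna(rng, 100000), locus, 1000, 6000, 600, 1.0, 1.0, rng, target_fraction=0.0
        )
        lengths = np.array([len(m) for m in mols])
        se = 600 / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 6000) < 2 * se

    def test_invalid_frag_mean(self, rng, element):
        tg = element + random_dna(rng, 100)
        locus = build_locus("ACGT", tg, "ACGT", element)
        with pytest.raises(ValueError):
            shear_circularize("ACGT" * 1000, locus, 10, frag_mean=0, rng=rng)


class TestInversePcr:
    def circle_with_element(self, rng, element, length=3000, rotate=0):
        filler = random_dna(rng, length - len(element))
        seq = element + filler
        seq = seq[rotate:] + seq[:rotate]
        return CircularMolecule(id="c", seq=seq, origin=("locus", 0, length))

    def test_no_primer_sites_no_product(self, rng):
        circle = CircularMolecule(id="c", seq=random_dna(rng, 3000), origin=("bg", 0, 3000))
        assert inverse_pcr(circle) is None

    def test_linear_molecule_no_product(self, rng, element):
        circle = self.circle_with_element(rng, element)
        circle.circular = False
        assert inverse_pcr(circle) is None

    def test_product_is_circle_minus_gap(self, rng, element):
        circle = self.circle_with_element(rng, element, length=3000)
        amp = inverse_pcr(circle)
        assert amp is not None
        # gap between the plus-strand end of the R site and the F start is 80
        assert len(amp) == 3000 - 80
        assert amp.seq.startswith(P35S_FORWARD)
        assert amp.seq.endswith(reverse_complement(P35S_REVERSE))

    def test_amplicon_is_substring_of_doubled_circle(self, rng, element):
        for rotate in (0, 137, 1500, 2711):
            circle = self.circle_with_element(rng, element, rotate=rotate)
            amp = inverse_pcr(circle)
            assert amp is not None
            assert amp.seq in circle.seq + circle.seq

    def test_junction_position_recorded(self, rng, element):
        # rotation puts the stored-origin (shear junction) inside the product
        circle = self.circle_with_element(rng, element, rotate=1500)
        amp = inverse_pcr(circle)
        assert amp.shear_junction_pos is not None
        assert 0 < amp.shear_junction_pos < len(amp)
        assert len(amp.truth_segments) == 2

    def test_product_is_strand_invariant(self, rng, element):
        # the same circle stored in the opposite orientation amplifies to
        # the identical product (PCR does not know which strand was stored)
        circle = self.circle_with_element(rng, element, length=3000)
        flipped = CircularMolecule(
            id="c_rc", seq=reverse_complement(circle.seq), origin=circle.origin
        )
        amp, amp_rc = inverse_pcr(circle), inverse_pcr(flipped)
        assert amp is not None and amp_rc is not None
        assert amp.seq == amp_rc.seq

    def test_too_short_circle(self, element):
        circle = CircularMolecule(id="c", seq="ACGT" * 5, origin=("bg", 0, 20))
        assert inverse_pcr(circle) is None


class TestSimulateReads:
    def amplicon(self, rng, n=2000):
        seq = P35S_FORWARD + random_dna(rng, n) + reverse_complement(P35S_REVERSE)
        return Amplicon(
            id="a0",
            seq=seq,
            source_circle="c0",
            primer_f_interval=(0, 22),
            primer_r_interval=(len(seq) - 22, len(seq)),
            truth_segments=[("locus", 0, len(seq))],
        )

    def test_noiseless_reads_are_exact_substrings(self, rng):
        amp = self.amplicon(rng)
        model = ErrorModel(sub_rate=0, ins_rate=0, del_rate=0, mean_read_len=500, read_len_sd=100)
        reads = simulate_reads([amp], model, n_reads=50, rng=rng)
        for r in reads:
            _, (s, e), strand = r.truth
            t = amp.seq[s:e]
            if strand == "-":
                t = reverse_complement(t)
            assert r.seq == t

    def test_mean_accuracy_matches_error_model(self, rng):
        amp = self.amplicon(rng, n=4000)
        model = ErrorModel(mean_read_len=1500, read_len_sd=300)
        reads = simulate_reads([amp], model, n_reads=800, rng=rng)
        accs = []
        for r in reads:
            _, (s, e), strand = r.truth
            t = amp.seq[s:e]
            if strand == "-":
                t = reverse_complement(t)
            d = edlib.align(r.seq, t, mode="NW")["editDistance"]
            accs.append(1 - d / (e - s))
        mean_acc = float(np.mean(accs))
        assert 0.935 <= mean_acc <= 0.945

    def test_deterministic_given_seed(self, rng):
        amp = self.amplicon(rng)
        model = ErrorModel()
        a = simulate_reads([amp], model, n_reads=20, rng=123)
        b = simulate_reads([amp], model, n_reads=20, rng=123)
        assert [(r.id, r.seq, list(r.quals)) for r in a] == [
            (r.id, r.seq, list(r.quals)) for r in b
        ]

    def test_empty_amplicon_list_warns(self):
        with pytest.warns(UserWarning):
            assert simulate_reads([], ErrorModel(), n_reads=10, rng=0) == []


class TestSimulatedRunGeometry:
    def test_background_molecules_never_amplify(self, small_run):
        assert all(a.truth_segments[0][0] == "locus" for a in small_run.amplicons)

    def test_amplicons_substrings_of_doubled_circles(self, small_run):
        circles = {m.id: m for m in small_run.molecules}
        for a in small_run.amplicons[:50]:
            c = circles[a.source_circle]
            doubled = c.seq + c.seq
            assert a.seq in doubled or reverse_complement(a.seq) in doubled

    def test_run_is_seed_deterministic(self):
        kw = dict(
            flank5_len=500, transgene_len=1200, flank3_len=500, p35s_offset=400,
            background_len=5000, n_molecules=300, frag_mean=1200.0, frag_sd=120.0,
            n_reads=50,
        )
        a = simulate_run(seed=9, **kw)
        b = simulate_run(seed=9, **kw)
        assert [(r.id, r.seq) for r in a.reads] == [(r.id, r.seq) for r in b.reads]
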