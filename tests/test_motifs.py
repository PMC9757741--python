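import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitecoopt.core_genomics import GenomicInterval
from mitecoopt.motifs import (
    PWM,
    MotifOccurrence,
    integer_score_table,
    pair_and_classify,
    periodicity_share,
    read_meme,
    scan_pwm,
    symmetrized_composition,
    tt_periodicity,
    write_meme,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def random_pwm(rng, width, name="m"):
    probs = rng.dirichlet(np.ones(4), size=width)
    return PWM(name, probs)


def occ(motif, chrom, start, width, strand):
    return MotifOccurrence(
        motif, GenomicInterval(chrom, start, start + width, strand), 0.0, 0.0
    )


class TestPWMValidation:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PWM("m", np.full((5, 4), 0.3))

    def test_minimum_width(self):
        with pytest.raises(ValueError):
            PWM("m", np.full((3, 4), 0.25))

    def test_all_zero_base_column_rejected(self):
        probs = np.array(
            [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [1, 0, 0, 0]], dtype=float
        )
        with pytest.raises(ValueError):
            PWM("m", probs)


class TestExactPValues:
    """The DP survival function must agree with brute-force enumeration of
    every k-mer, for all widths up to 8 (both use the same discretized
    integer scores; the enumeration is independent of the DP recursion)."""

    @pytest.mark.parametrize("width", [4, 5, 6, 7, 8])
    def test_dp_equals_enumeration(self, width):
        rng = np.random.default_rng(width)
        for bg in (np.full(4, 0.25), np.array([0.3, 0.2, 0.2, 0.3])):
            pwm = random_pwm(rng, width)
            ints, survival, _ = integer_score_table(pwm, bg)
            digits = (
                np.arange(4**width)[:, None] // 4 ** np.arange(width)[::-1]
            ) % 4
            scores = ints[np.arange(width)[None, :], digits].sum(axis=1)
            probs = bg[digits].prod(axis=1)
            pdf = np.bincount(scores, weights=probs, minlength=len(survival))
            brute = pdf[::-1].cumsum()[::-1]
            assert np.allclose(brute, survival, atol=1e-12)

    def test_uniform_background_width6_hexamer_oracle(self):
        rng = np.random.default_rng(0)
        pwm = random_pwm(rng, 6)
        bg = np.full(4, 0.25)
        ints, survival, _ = integer_score_table(pwm, bg)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        hits = scan_pwm(seq, pwm, p_threshold=1.0, background=bg)
        digits = (np.arange(4**6)[:, None] // 4 ** np.arange(6)[::-1]) % 4
        kmer_scores = ints[np.arange(6)[None, :], digits].sum(axis=1)
        code = {b: i for i, b in enumerate("ACGT")}
        for h in (x for x in hits if x.interval.strand == "+"):
            window = seq[h.interval.start : h.interval.end]
            score = sum(
                ints[j, code[b]] for j, b in enumerate(window)
            )
            expected = np.mean(kmer_scores >= score)  # uniform bg: plain fraction
            assert h.pvalue == pytest.approx(expected, abs=1e-12)


class TestScan:
    def test_indicator_pwm_single_hit(self):
        target = "AAAACCCC"
        pwm = PWM.from_consensus("m", target, major_prob=0.97)
        hits = scan_pwm(target, pwm, p_threshold=0.0005, background=np.full(4, 0.25))
        assert len(hits) == 1
        h = hits[0]
        assert (h.interval.start, h.interval.end, h.interval.strand) == (0, 8, "+")

    def test_strand_symmetry(self, rng):
        pwm = random_pwm(rng, 7)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        fwd = scan_pwm(seq, pwm, p_threshold=0.05)
        rev = scan_pwm(revcomp(seq), pwm, p_threshold=0.05)
        flip = {"+": "-", "-": "+"}
        mirrored = {
            (len(seq) - h.interval.end, flip[h.interval.strand], round(h.pvalue, 12))
            for h in rev
        }
        original = {
            (h.interval.start, h.interval.strand, round(h.pvalue, 12)) for h in fwd
        }
        assert original == mirrored

    def test_windows_with_n_are_skipped(self):
        pwm = PWM.from_consensus("m", "ACGTAC", major_prob=0.97)
        hits = scan_pwm("ACGTNC" + "ACGTAC", pwm, p_threshold=0.01)
        assert all(h.interval.start >= 6 or h.interval.strand == "-" for h in hits)

    def test_lowering_threshold_never_adds_hits(self, rng):
        pwm = random_pwm(rng, 6)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        loose = {
            (h.interval.start, h.interval.strand)
            for h in scan_pwm(seq, pwm, p_threshold=0.01)
        }
        tight = {
            (h.interval.start, h.interval.strand)
            for h in scan_pwm(seq, pwm, p_threshold=0.001)
        }
        assert tight <= loose


class TestPairAndClassify:
    def test_divergent_gap14_is_cerp2_like(self):
        m1 = occ("m1", "chrI", 100, 12, "-")
        m2 = occ("m2", "chrI", 126, 10, "+")  # gap = 126 - 112 = 14
        (pair,) = pair_and_classify([m1], [m2])
        assert pair.arrangement == "divergent"
        assert pair.spacing == 14
        assert pair.family == "CERP2_like"

    def test_tandem_m2_m1_gap25_is_cele2_like(self):
        m2 = occ("m2", "chrI", 100, 10, "+")
        m1 = occ("m1", "chrI", 135, 12, "+")  # gap = 135 - 110 = 25
        (pair,) = pair_and_classify([m1], [m2])
        assert pair.arrangement == "tandem_m2_m1"
        assert pair.spacing == 25
        assert pair.family == "CELE2_like"

    def test_convergent(self):
        m1 = occ("m1", "chrI", 100, 12, "+")
        m2 = occ("m2", "chrI", 130, 10, "-")
        (pair,) = pair_and_classify([m1], [m2])
        assert pair.arrangement == "convergent"

    def test_tandem_on_minus_strand_uses_5prime_order(self):
        # both on '-': 5'->3' runs right to left, so the rightmost motif is first
        m1 = occ("m1", "chrI", 130, 12, "-")
        m2 = occ("m2", "chrI", 100, 10, "-")
        (pair,) = pair_and_classify([m1], [m2])
        assert pair.arrangement == "tandem_m1_m2"

    def test_gap31_not_emitted(self):
        m1 = occ("m1", "chrI", 100, 12, "+")
        m2 = occ("m2", "chrI", 143, 10, "+")  # gap 31
        assert pair_and_classify([m1], [m2]) == []

    def test_overlapping_occurrences_excluded(self):
        m1 = occ("m1", "chrI", 100, 12, "+")
        m2 = occ("m2", "chrI", 105, 10, "+")
        assert pair_and_classify([m1], [m2]) == []

    def test_one_m1_pairs_with_multiple_m2(self):
        m1 = occ("m1", "chrI", 100, 12, "+")
        m2s = [occ("m2", "chrI", 127, 10, "+"), occ("m2", "chrI", 70, 10, "+")]
        assert len(pair_and_classify([m1], m2s)) == 2

    @given(data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_reverse_complement_symmetry(self, data):
        length = 10_000
        n1 = data.draw(st.integers(1, 4))
        n2 = data.draw(st.integers(1, 4))

        def draw_hits(motif, width, n):
            out = []
            for _ in range(n):
                start = data.draw(st.integers(0, length - width))
                strand = data.draw(st.sampled_from("+-"))
                out.append(occ(motif, "chrI", start, width, strand))
            return out

        m1s, m2s = draw_hits("m1", 12, n1), draw_hits("m2", 10, n2)
        flip = {"+": "-", "-": "+"}

        def rc(h):
            ivl = h.interval
            return occ(h.motif, "chrI", length - ivl.end, ivl.length, flip[ivl.strand])

        fwd = pair_and_classify(m1s, m2s)
        rev = pair_and_classify([rc(h) for h in m1s], [rc(h) for h in m2s])
        key_fwd = sorted((p.arrangement, p.family, p.spacing) for p in fwd)
        key_rev = sorted((p.arrangement, p.family, p.spacing) for p in rev)
        assert key_fwd == key_rev


class TestTTPeriodicity:
    def test_all_a_sequences_score_zero(self):
        profile, score = tt_periodicity(["A" * 60] * 5)
        assert np.all(profile == 0)
        assert score == 0.0

    def test_too_short_sequences_raise(self):
        with pytest.raises(ValueError):
            tt_periodicity(["A"])

    def test_planted_period10_dominates_other_periods(self):
        # one TT per sequence, offset drawn from a period-10 cosine density,
        # so the mean profile is a pure period-10 sinusoid over background
        rng = np.random.default_rng(0)
        offsets = np.arange(100)
        density = 1.0 + np.cos(2 * np.pi * offsets / 10)
        density /= density.sum()
        seqs = []
        for _ in range(3000):
            chars = list("".join("ACG"[i] for i in rng.integers(0, 3, 102)))
            pos = int(rng.choice(offsets, p=density))
            chars[pos : pos + 2] = "TT"
            seqs.append("".join(chars))
        profile, score = tt_periodicity(seqs)
        others = [periodicity_share(profile, p) for p in (5, 7, 8, 9, 11, 12, 15, 20)]
        assert score > max(others)
        assert score > 0.5

    def test_uniform_sequences_flat_profile(self):
        rng = np.random.default_rng(1)
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 80)) for _ in range(4000)]
        profile, _ = tt_periodicity(seqs)
        # binomial CI around 1/16 with n = 4000 sequences per offset
        se = np.sqrt((1 / 16) * (15 / 16) / 4000)
        assert np.all(np.abs(profile - 1 / 16) < 5 * se)


class TestMemeIO:
    def test_round_trip(self, tmp_path, rng):
        pwms = [random_pwm(rng, 8, "m1"), random_pwm(rng, 5, "m2")]
        path = tmp_path / "motifs.meme"
        write_meme(pwms, path)
        back = read_meme(path)
        assert [p.name for p in back] == ["m1", "m2"]
        for a, b in zip(pwms, back):
            assert np.allclose(a.probs, b.probs, atol=1e-5)


def test_symmetrized_composition_is_strand_symmetric():
    comp = symmetrized_composition(["AAAACGT"])
    assert comp[0] == comp[3] and comp[1] == comp[2]
    assert comp.sum() == pytest.approx(1.0)
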