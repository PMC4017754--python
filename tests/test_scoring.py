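"""Conservation-score component tests: worked values, boundaries, properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g4conserve import (
    CoordinateError,
    InputError,
    ScanParams,
    ScoringParams,
    conservation_score,
    find_qgrs,
    length_similarity,
    loop_similarity,
    overlap_score,
    semiglobal_align,
    tetrad_similarity,
)


class TestOverlapScore:
    def test_identical_intervals_saturate(self):
        assert overlap_score((10, 30), (10, 30), 20) == 1.0

    def test_disjoint_padded_intervals_zero(self):
        assert overlap_score((0, 10), (200, 210), 10) == 0.0

    def test_ninety_percent_raw_overlap_saturates(self):
        # padded [1,39) vs [3,41): intersection 36, union 40 -> raw 0.90 >= 0.85
        assert overlap_score((10, 30), (12, 32), 18) == 1.0

    def test_interval_arithmetic_below_saturation(self):
        # [10,30) vs [18,38), smaller 20 -> padded [0,40) vs [8,48):
        # raw = 32/48 = 2/3 -> 2/3 / 0.85
        expected = (32 / 48) / 0.85
        assert overlap_score((10, 30), (18, 38), 20) == pytest.approx(expected)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(CoordinateError):
            overlap_score((5, 5), (0, 10), 10)

    def test_symmetric_under_swap(self):
        a, b = (3, 17), (9, 40)
        assert overlap_score(a, b, 14) == overlap_score(b, a, 14)

    def test_smaller_denominator_mode(self):
        params = ScoringParams(overlap_denominator="smaller")
        # padded [0,40) vs [8,48): intersection 32, smaller span 40
        assert overlap_score((10, 30), (18, 38), 20, params) == pytest.approx(
            (32 / 40) / 0.85
        )


class TestTetradSimilarity:
    @pytest.mark.parametrize(
        "ta,tb,expected",
        [
            (3, 4, 0.75),
            (2, 4, 0.0),
            (3, 3, 1.0),
            (2.75, 3, 2.75 / 3),
            (2, 4.0, 0.0),  # ratio exactly 0.5 is zeroed ("at or below")
        ],
    )
    def test_values(self, ta, tb, expected):
        assert tetrad_similarity(ta, tb) == pytest.approx(expected)

    def test_symmetric(self):
        assert tetrad_similarity(2.5, 4) == tetrad_similarity(4, 2.5)


class TestLoopSimilarity:
    def test_identical_triples(self):
        assert loop_similarity((3, 1, 7), (3, 1, 7)) == 1.0

    def test_all_ratios_below_floor_zero(self):
        assert loop_similarity((2, 2, 2), (5, 5, 5)) == 0.0

    def test_kiss1_loop_triples(self):
        # human (7,3,16) vs mouse (8,4,3): (0.875 + 0.75 + 0)/3
        assert loop_similarity((7, 3, 16), (8, 4, 3)) == pytest.approx(
            (7 / 8 + 3 / 4 + 0) / 3
        )

    def test_ratio_exactly_half_is_kept(self):
        # "less than 50" is zeroed; exactly 0.5 survives
        assert loop_similarity((1, 1, 1), (2, 1, 1)) == pytest.approx((0.5 + 2) / 3)

    def test_zero_against_zero_is_perfect(self):
        assert loop_similarity((0, 2, 2), (0, 2, 2)) == 1.0

    def test_zero_against_nonzero_scores_zero(self):
        assert loop_similarity((0, 2, 2), (3, 2, 2)) == pytest.approx(2 / 3)

    def test_positional_pairing_not_best_match(self):
        # same multisets but misaligned positions score below 1
        assert loop_similarity((1, 9, 9), (9, 9, 1)) < 1.0


class TestLengthSimilarity:
    @pytest.mark.parametrize(
        "la,lb,expected",
        [
            (30, 30, 1.0),
            (24, 40, 0.0),  # ratio exactly 0.6 -> zero ("60% ... or lower")
            (32, 40, 0.5),  # ratio 0.8 -> (0.8-0.6)/0.4
            (10, 40, 0.0),
        ],
    )
    def test_values(self, la, lb, expected):
        assert length_similarity(la, lb) == pytest.approx(expected)


class TestConservationScore:
    def test_identical_pair_scores_exactly_one(self):
        seq = "TTACCGGGTTGGGCAGGGTTAGGGTTACC"
        motifs = find_qgrs(seq, sequence_id="a")
        aln = semiglobal_align(seq, seq)
        best = max(motifs, key=lambda m: m.g_score)
        comp = conservation_score(best, best, aln)
        assert comp.composite == 1.0
        assert (comp.overlap, comp.tetrad, comp.loop, comp.length) == (1, 1, 1, 1)

    def test_weighted_sum_of_printed_kiss1_structure(self):
        # overlap saturated, tetrads 2 vs 4, loops (7,3,16) vs (8,4,3),
        # lengths 42 vs 23 -> 0.65 + 0.10 * 0.541667 = 0.704167
        ov, te = 1.0, tetrad_similarity(2, 4)
        lo = loop_similarity((7, 3, 16), (8, 4, 3))
        le = length_similarity(42, 23)
        composite = 0.65 * ov + 0.20 * te + 0.10 * lo + 0.05 * le
        print(
            f"components: overlap={ov:.6f} tetrad={te:.6f} "
            f"loop={lo:.6f} length={le:.6f} composite={composite:.6f}"
        )
        assert te == 0.0 and le == 0.0
        assert composite == pytest.approx(0.65 + 0.10 * (7 / 8 + 3 / 4) / 3)
        assert composite == pytest.approx(0.704167, abs=5e-7)

    def test_distant_motifs_are_disposable(self):
        p = "GGTTGGTTGGTTGG" + "ACT" * 60
        c = "ACT" * 60 + "GGTTGGTTGGTTGG"
        mp = find_qgrs(p, ScanParams(min_loop_length=1), "p")[0]
        mc = find_qgrs(c, ScanParams(min_loop_length=1), "c")[0]
        comp = conservation_score(mp, mc, semiglobal_align(p, c))
        assert comp.overlap == 0.0
        assert comp.disposable

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        s1=st.integers(0, 200),
        l1=st.integers(1, 45),
        s2=st.integers(0, 200),
        l2=st.integers(1, 45),
        t1=st.floats(2, 6),
        t2=st.floats(2, 6),
        loops=st.tuples(*[st.integers(0, 36)] * 6),
        lens=st.tuples(st.integers(8, 45), st.integers(8, 45)),
    )
    def test_components_in_unit_interval(self, s1, l1, s2, l2, t1, t2, loops, lens):
        ov = overlap_score((s1, s1 + l1), (s2, s2 + l2), min(l1, l2))
        te = tetrad_similarity(t1, t2)
        lo = loop_similarity(loops[:3], loops[3:])
        le = length_similarity(*lens)
        for v in (ov, te, lo, le):
            assert 0.0 <= v <= 1.0
        composite = 0.65 * ov + 0.2 * te + 0.1 * lo + 0.05 * le
        assert 0.0 <= composite <= 1.0
        # symmetry of the structural components
        assert te == tetrad_similarity(t2, t1)
        assert lo == loop_similarity(loops[3:], loops[:3])
        assert le == length_similarity(lens[1], lens[0])


class TestScoringParams:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(InputError):
            ScoringParams(w_overlap=0.7)

    def test_thresholds_must_be_fractional(self):
        with pytest.raises(InputError):
            ScoringParams(overlap_saturation=1.5)
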