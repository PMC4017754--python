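"""Scanner unit and property tests: enumeration, fractional tetrads, G-score."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g4conserve import (
    CoordinateError,
    InputError,
    QGRSMotif,
    ScanParams,
    default_g_score,
    find_qgrs,
    motif_fractional_tetrads,
    normalize_sequence,
)

from _oracles import enumerate_qgrs_bruteforce

GREB1_FRAGMENT = "GGATGAGCCTGTGGGTGGAGGGCAGTGGAGCGGGCTGGG"
FRACTIONAL_EXAMPLE = "GGGACGTTCGGATTGGGTTACCAGGG"  # G-runs 3, 2, 3, 3


def as_tuples(motifs):
    return {(m.start, m.tetrads, *m.loops) for m in motifs}


class TestNormalize:
    def test_uppercase_and_u_to_t(self):
        assert normalize_sequence("acgu") == "ACGT"

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            normalize_sequence("")

    def test_illegal_character_named(self):
        with pytest.raises(InputError, match="'X'"):
            normalize_sequence("ACGX")


class TestFindQgrs:
    def test_no_g_tracts_yields_nothing(self):
        assert find_qgrs("ATCGATCGATCG") == []

    def test_overlapping_motifs_all_reported(self):
        motifs = find_qgrs(GREB1_FRAGMENT)
        assert len(motifs) > 1
        # mutually overlapping motifs exist
        overlapping = any(
            m1.start < m2.end and m2.start < m1.end
            for i, m1 in enumerate(motifs)
            for m2 in motifs[i + 1 :]
        )
        assert overlapping
        assert as_tuples(motifs) == enumerate_qgrs_bruteforce(GREB1_FRAGMENT)

    def test_three_tetrad_motif_spans_printed_lrp5_sequence(self):
        seq = "GGGGTGGGCAGGGCTGGG"
        motifs = find_qgrs(seq, ScanParams(min_tetrads=3))
        spanning = [m for m in motifs if m.tetrads == 3 and m.length == len(seq)]
        assert spanning and spanning[0].motif_string == seq

    def test_two_tetrad_motif_unique_with_min_loop_one(self):
        motifs = find_qgrs("GGTTGGTTGGTTGG", ScanParams(min_loop_length=1))
        assert as_tuples(motifs) == {(0, 2, 2, 2, 2)}
        assert as_tuples(motifs) == enumerate_qgrs_bruteforce(
            "GGTTGGTTGGTTGG", min_loop_length=1
        )

    def test_sorted_by_start_then_descending_g_score(self):
        motifs = find_qgrs(GREB1_FRAGMENT)
        keys = [(m.start, -m.g_score) for m in motifs]
        assert keys == sorted(keys)

    def test_motif_string_reextracts(self):
        for m in find_qgrs(GREB1_FRAGMENT):
            assert GREB1_FRAGMENT[m.start : m.end] == m.motif_string
            # declared decomposition matches: all four tracts are G-runs
            for t in m.tract_starts:
                assert m.motif_string[t - m.start : t - m.start + m.tetrads] == (
                    "G" * m.tetrads
                )

    def test_rna_input_accepted(self):
        assert as_tuples(find_qgrs("GGUUGGUUGGUUGG")) == as_tuples(
            find_qgrs("GGTTGGTTGGTTGG")
        )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60), st.integers(0, 10**6))
    def test_matches_bruteforce_on_random_sequences(self, seq, salt):
        del salt  # widens the explored space
        assert as_tuples(find_qgrs(seq)) == enumerate_qgrs_bruteforce(seq)

    def test_gc_rich_sequence_matches_bruteforce(self):
        rng = random.Random(7)
        for _ in range(25):
            seq = "".join(rng.choice("GGGCAT") for _ in range(50))
            assert as_tuples(find_qgrs(seq)) == enumerate_qgrs_bruteforce(seq)


class TestFractionalTetrads:
    def test_printed_example_is_2_75(self):
        motifs = [m for m in find_qgrs(FRACTIONAL_EXAMPLE) if m.tetrads == 2]
        assert motifs
        assert all(m.fractional_tetrads == 2.75 for m in motifs)

    def test_exact_runs_add_nothing(self):
        (motif,) = find_qgrs("GGTTGGTTGGTTGG", ScanParams(min_loop_length=1))
        assert motif.fractional_tetrads == 2.0

    def test_runs_longer_than_x_counted(self):
        # G-runs 4, 2, 3, 2: oracle = x + (#runs longer than x)/4 = 2.5
        seq = "GGGGTTGGTTGGGTTGG"
        motifs = [
            m
            for m in find_qgrs(seq, ScanParams(min_loop_length=1))
            if m.tetrads == 2 and len(set(m.tract_starts) & {6, 15}) == 2
        ]
        full = [m for m in motifs if m.start in (0, 1, 2) and m.end == 17]
        assert full and all(m.fractional_tetrads == 2.5 for m in full)

    def test_fraction_always_quarter_valued(self):
        for m in find_qgrs(GREB1_FRAGMENT):
            assert m.fractional_tetrads - m.tetrads in (0.0, 0.25, 0.5, 0.75)

    def test_out_of_range_coordinates_rejected(self):
        motif = QGRSMotif(
            sequence_id="x",
            start=5,
            tetrads=2,
            loops=(2, 2, 2),
            motif_string="GGTTGGTTGGTTGG",
            g_score=0.0,
            fractional_tetrads=2.0,
        )
        with pytest.raises(CoordinateError):
            motif_fractional_tetrads(motif, "GGTTGGTTGGTTGG")


class TestGScore:
    def test_increasing_in_tetrads(self, scan_params):
        assert default_g_score(3, (2, 2, 2), scan_params) > default_g_score(
            2, (2, 2, 2), scan_params
        )

    def test_decreasing_in_loop_spread_at_fixed_mean(self, scan_params):
        assert default_g_score(2, (2, 2, 2), scan_params) > default_g_score(
            2, (1, 2, 3), scan_params
        )

    def test_stated_default_arithmetic(self, scan_params):
        expected = 10 * (1 - 2 / 36) + 10  # x=2, loops (2,2,2), Ymax=36
        assert default_g_score(2, (2, 2, 2), scan_params) == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        x=st.integers(2, 6),
        loops=st.tuples(st.integers(0, 36), st.integers(0, 36), st.integers(0, 36)),
    )
    def test_monotonicity_properties(self, scan_params, x, loops):
        g = default_g_score(x, loops, scan_params)
        assert default_g_score(x + 1, loops, scan_params) > g
        # shrinking the longest loop raises the score (mean and spread shrink)
        longest = max(range(3), key=lambda k: loops[k])
        if loops[longest] > min(loops):
            shorter = list(loops)
            shorter[longest] -= 1
            assert default_g_score(x, tuple(shorter), scan_params) > g


class TestScanParams:
    def test_min_tetrads_below_two_rejected(self):
        with pytest.raises(InputError):
            ScanParams(min_tetrads=1)

    def test_inconsistent_loop_bounds_rejected(self):
        with pytest.raises(InputError):
            ScanParams(min_loop_length=5, max_loop_length=2)

    def test_motif_length_must_fit_minimal_motif(self):
        with pytest.raises(InputError):
            ScanParams(min_tetrads=3, max_motif_length=11)
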