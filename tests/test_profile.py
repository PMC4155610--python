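"""Profile counting, normalization, merging, consensus."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from profilegrid import (
    ProfileError,
    build_profile,
    compute_consensus,
    make_alignment,
    merge_profiles,
    normalize,
    parse_profile_tsv,
)

from ._oracles import naive_consensus, naive_profile, random_records
from .conftest import TOY4_RECORDS


class TestBuildProfile:
    def test_toy4_counts(self, toy4_profile):
        expected = {("A", 1): 3, ("G", 1): 1, ("C", 2): 3, ("-", 2): 1,
                    ("D", 3): 3, ("E", 3): 1}
        for sym in toy4_profile.row_alphabet:
            for col in (1, 2, 3):
                assert toy4_profile.count(sym, col) == expected.get((sym, col), 0)

    def test_clean_alignment_has_21_rows(self, toy4_profile):
        assert len(toy4_profile.row_alphabet) == 21
        assert toy4_profile.counts.shape[0] == 21

    def test_single_sequence_indicator(self):
        p = build_profile(make_alignment([("s", "MW")]))
        assert p.count("M", 1) == 1 and p.count("W", 2) == 1
        assert p.counts.sum() == 2

    def test_doubling_doubles_counts(self, toy4, toy4_profile):
        doubled = make_alignment(
            list(toy4.records) + [(f"{rid}b", seq) for rid, seq in toy4.records]
        )
        assert np.array_equal(build_profile(doubled).counts, 2 * toy4_profile.counts)

    def test_ambiguity_codes_fold_to_x_row(self):
        p = build_profile(make_alignment([("s1", "AB"), ("s2", "AZ")]))
        assert p.row_alphabet[-1] == "X"
        assert len(p.row_alphabet) == 22
        assert p.count("X", 2) == 2

    def test_record_order_irrelevant(self, toy4, toy4_profile):
        shuffled = list(toy4.records)
        random.Random(5).shuffle(shuffled)
        assert np.array_equal(build_profile(make_alignment(shuffled)).counts,
                              toy4_profile.counts)

    def test_matches_naive_tally(self):
        rng = random.Random(11)
        records = random_records(rng, 40, 25)
        p = build_profile(make_alignment(records))
        tally = naive_profile(records)
        for r, sym in enumerate(p.row_alphabet):
            for c in range(1, p.length + 1):
                assert p.counts[r, c - 1] == tally.get((sym, c), 0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(1, 30), st.integers(1, 20), st.integers(0, 10_000))
    def test_columns_conserve_depth(self, n, length, seed):
        records = random_records(random.Random(seed), n, length)
        p = build_profile(make_alignment(records))
        assert (p.counts.sum(axis=0) == n).all()
        f = normalize(p)
        assert np.allclose(f.freqs.sum(axis=0), 1.0, atol=1e-9)


class TestNormalize:
    def test_toy4_frequencies(self, toy4_freqs):
        assert toy4_freqs.frequency("A", 1) == pytest.approx(0.75)
        assert toy4_freqs.frequency("G", 1) == pytest.approx(0.25)

    def test_indicator_column(self):
        f = normalize(build_profile(make_alignment([("s", "M")])))
        assert f.frequency("M", 1) == 1.0
        assert f.freqs.sum() == 1.0

    def test_scale_invariance(self, toy4, toy4_freqs):
        doubled = make_alignment(
            list(toy4.records) + [(f"{rid}b", seq) for rid, seq in toy4.records]
        )
        assert np.allclose(normalize(build_profile(doubled)).freqs, toy4_freqs.freqs)


class TestMergeProfiles:
    def test_additivity(self, toy4, toy4_profile):
        merged = merge_profiles(toy4_profile, toy4_profile)
        doubled = build_profile(make_alignment(
            list(toy4.records) + [(f"{rid}b", seq) for rid, seq in toy4.records]
        ))
        assert np.array_equal(merged.counts, doubled.counts)
        assert merged.depth == doubled.depth == 8

    def test_merge_with_all_gap_alignment(self, toy4_profile):
        gaps = build_profile(make_alignment([("g1", "---"), ("g2", "---")]))
        merged = merge_profiles(toy4_profile, gaps)
        assert merged.count("-", 2) == toy4_profile.count("-", 2) + 2
        assert merged.count("A", 1) == toy4_profile.count("A", 1)

    def test_length_mismatch_rejected(self, toy4_profile):
        other = build_profile(make_alignment([("a", "AC")]))
        with pytest.raises(ProfileError, match="length"):
            merge_profiles(toy4_profile, other)

    def test_alphabet_mismatch_rejected(self, toy4_profile):
        with_x = build_profile(make_alignment([("a", "ABD")]))
        with pytest.raises(ProfileError, match="alphabet"):
            merge_profiles(toy4_profile, with_x)


class TestConsensus:
    def test_toy4_plurality(self, toy4_profile):
        cons = compute_consensus(toy4_profile, "eligible")
        assert cons.symbols == "ACD"
        assert all(not t for t in cons.ties)

    def test_tie_breaks_alphabetically_and_is_recorded(self):
        p = build_profile(make_alignment([("a", "AA"), ("b", "GG")]))
        cons = compute_consensus(p)
        assert cons.symbols == "AA"
        assert cons.ties == (frozenset("AG"), frozenset("AG"))

    def test_gap_policy_changes_gap_majority_column(self):
        p = build_profile(make_alignment(
            [("a", "-"), ("b", "-"), ("c", "-"), ("d", "K")]))
        assert compute_consensus(p, "eligible").symbols == "-"
        assert compute_consensus(p, "excluded").symbols == "K"

    def test_all_gap_column_excluded_policy_flagged(self):
        p = build_profile(make_alignment([("a", "-"), ("b", "-")]))
        cons = compute_consensus(p, "excluded")
        assert cons.symbols == "-"
        assert cons.ties[0] == frozenset({"-"})

    def test_depth_one_consensus_is_the_sequence(self):
        seq = "MW-KD"
        p = build_profile(make_alignment([("s", seq)]))
        assert compute_consensus(p, "eligible").symbols == seq

    def test_matches_naive_consensus_both_policies(self):
        rng = random.Random(23)
        records = random_records(rng, 30, 15)
        p = build_profile(make_alignment(records))
        for policy in ("eligible", "excluded"):
            assert compute_consensus(p, policy).symbols == \
                naive_consensus(records, policy)

    def test_unknown_policy_rejected(self, toy4_profile):
        with pytest.raises(ProfileError, match="gap_policy"):
            compute_consensus(toy4_profile, "majority")


class TestTsvExport:
    def test_count_round_trip(self, toy4_profile):
        symbols, counts = parse_profile_tsv(toy4_profile.to_tsv())
        assert symbols == toy4_profile.row_alphabet
        assert np.array_equal(counts, toy4_profile.counts)

    def test_frequency_fixed_precision(self):
        f = normalize(build_profile(make_alignment([("s", "M")])))
        assert "1.000000" in f.to_tsv()

    def test_zero_rows_not_dropped(self, toy4_profile):
        assert toy4_profile.to_tsv().count("\n") == 22  # header + 21 rows
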